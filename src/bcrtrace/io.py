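"""Reading, validation and filtering of single-cell V(D)J contig tables.

Two input dialects are supported: the AIRR Rearrangement TSV (MiAIRR
column names) and the 10x Genomics ``filtered_contig_annotations.csv``
layout. 10x columns are mapped onto AIRR names on read, so every
downstream module consumes a single canonical schema.

Canonical columns (a superset may be present; extras are carried along):

========================  =====================================================
sequence_id               unique contig identifier
cell_id                   cell barcode
locus                     IGH / IGK / IGL
v_call, d_call, j_call    gene (+ allele) calls, e.g. ``IGHV3-23*01``
c_call                    constant gene, e.g. ``IGHG1``
productive                boolean
junction, junction_aa     junction nucleotide / amino-acid sequence
cdr3, cdr3_aa             CDR3 nucleotide / amino-acid sequence
read_count, umi_count     contig support
visit                     longitudinal sample label (e.g. d0_B, d5, d7)
sequence_alignment        IMGT-gapped V-region sequence
germline_alignment        IMGT-gapped germline of equal length
fwr1_start .. fwr3_end    region bounds, 0-based half-open, alignment coords
========================  =====================================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from bcrtrace.errors import ParameterError, SchemaError, ValidationError

AIRR_REQUIRED = ["sequence_id", "cell_id", "locus", "v_call", "j_call", "productive", "junction"]
TENX_REQUIRED = [
    "barcode",
    "contig_id",
    "chain",
    "v_gene",
    "j_gene",
    "c_gene",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
]

TENX_TO_AIRR = {
    "barcode": "cell_id",
    "contig_id": "sequence_id",
    "chain": "locus",
    "v_gene": "v_call",
    "d_gene": "d_call",
    "j_gene": "j_call",
    "c_gene": "c_call",
    "cdr3": "junction_aa",
    "cdr3_nt": "junction",
    "reads": "read_count",
    "umis": "umi_count",
}

REGIONS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3")
REGION_COLUMNS = [f"{r}_{end}" for r in REGIONS for end in ("start", "end")]

_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no", "none", ""}

def translate_nt(seq: str) -> str:
    """Translate a DNA string with the standard genetic code (Biopython).

    Trailing partial codons are dropped; ambiguous codons translate to 'X'.
    """
    from Bio.Seq import Seq

    trimmed = seq[: len(seq) - len(seq) % 3].upper()
    return str(Seq(trimmed).translate())


@dataclass
class ChainTable:
    """A validated table of rearranged receptor chains.

    Thin wrapper over a :class:`pandas.DataFrame` in the canonical AIRR-named
    schema. One row per contig; a cell may own several rows (multiple chains).
    """

    df: pd.DataFrame
    dialect: str = "airr"

    def __len__(self) -> int:
        return len(self.df)

    def heavy(self) -> pd.DataFrame:
        """Rows whose locus is IGH."""
        return self.df[self.df["locus"] == "IGH"]

    def light(self) -> pd.DataFrame:
        """Rows whose locus is IGK or IGL."""
        return self.df[self.df["locus"].isin(["IGK", "IGL"])]

    def copy(self) -> "ChainTable":
        return ChainTable(self.df.copy(), self.dialect)


def _normalize_bool(value) -> object:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return pd.NA
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"unrecognized boolean encoding: {value!r}")


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    fields = re.split(r"[\t,]", header.rstrip("\n"))
    if "barcode" in fields and "contig_id" in fields:
        return "tenx"
    return "airr"


def validate_table(df: pd.DataFrame) -> None:
    """Enforce the record-level invariants of the canonical schema."""
    dup = df["sequence_id"][df["sequence_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sequence_id values: {sorted(set(dup))[:5]}")

    for _, row in df.iterrows():
        v_call = row.get("v_call")
        locus = row.get("locus")
        if isinstance(v_call, str) and v_call and isinstance(locus, str):
            m = re.match(r"(IG[HKL])V", v_call)
            if m and m.group(1) != locus:
                raise ValidationError(
                    f"{row['sequence_id']}: locus {locus} inconsistent with v_call {v_call}"
                )
        seq_aln = row.get("sequence_alignment")
        germ_aln = row.get("germline_alignment")
        if isinstance(seq_aln, str) and isinstance(germ_aln, str):
            if len(seq_aln) != len(germ_aln):
                raise ValidationError(
                    f"{row['sequence_id']}: alignment lengths differ "
                    f"({len(seq_aln)} vs {len(germ_aln)})"
                )
            _validate_region_bounds(row, len(seq_aln))
        junction = row.get("junction")
        junction_aa = row.get("junction_aa")
        if (
            isinstance(junction, str)
            and isinstance(junction_aa, str)
            and junction
            and junction_aa
            and len(junction) % 3 == 0
        ):
            if translate_nt(junction) != junction_aa:
                raise ValidationError(
                    f"{row['sequence_id']}: junction_aa does not translate from junction"
                )


def _validate_region_bounds(row, alignment_length: int) -> None:
    prev_end = 0
    for region in REGIONS:
        start, end = row.get(f"{region}_start"), row.get(f"{region}_end")
        if pd.isna(start) or pd.isna(end):
            continue
        start, end = int(start), int(end)
        if not (0 <= start <= end <= alignment_length):
            raise ValidationError(f"{row['sequence_id']}: {region} bounds outside alignment")
        if start < prev_end:
            raise ValidationError(f"{row['sequence_id']}: {region} overlaps the previous region")
        prev_end = end


def read_contig_table(path, dialect: str = "auto") -> ChainTable:
    """Read a contig annotation table in the AIRR or 10x dialect.

    Parameters
    ----------
    path:
        TSV (AIRR) or CSV (10x ``filtered_contig_annotations.csv``) file.
    dialect:
        ``"airr"``, ``"tenx"``, or ``"auto"`` to sniff from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect not in ("airr", "tenx"):
        raise ParameterError(f"unknown dialect: {dialect!r}")

    if dialect == "tenx":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in TENX_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"tenx table missing required columns: {missing}")
        df = df.rename(columns=TENX_TO_AIRR)
        # 10x writes the literal string "None" for absent gene calls
        for col in ("v_call", "d_call", "j_call", "c_call", "junction", "junction_aa"):
            if col in df.columns:
                df[col] = df[col].replace({"None": pd.NA, "": pd.NA})
        df["cdr3"] = df["junction"]
        df["cdr3_aa"] = df["junction_aa"]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"airr table missing required columns: {missing}")
        df = df.replace({"": pd.NA})

    df["productive"] = df["productive"].map(_normalize_bool).astype("boolean")
    for col in ("read_count", "umi_count") + tuple(REGION_COLUMNS):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")

    validate_table(df)
    return ChainTable(df.reset_index(drop=True), dialect)


def write_airr(table: ChainTable, path) -> None:
    """Write a :class:`ChainTable` as an AIRR Rearrangement TSV.

    Booleans are encoded ``T``/``F`` (MiAIRR convention); missing values as
    empty fields. String and integer columns round-trip bit-exactly through
    :func:`read_contig_table`.
    """
    df = table.df.copy()
    if "productive" in df.columns:
        df["productive"] = df["productive"].map({True: "T", False: "F"}).astype("object")
    df.to_csv(path, sep="\t", index=False, na_rep="")


def filter_productive(table: ChainTable) -> ChainTable:
    """Keep only contigs with productive rearrangements (order preserved)."""
    kept = table.df[table.df["productive"].fillna(False).astype(bool)]
    return ChainTable(kept.reset_index(drop=True), table.dialect)


def resolve_cell_chains(table: ChainTable, read_ratio: float = 0.1) -> ChainTable:
    """Drop poorly supported extra chains within each (cell, locus) group.

    Within a group, a chain is kept iff its read count is at least
    ``read_ratio`` times the group maximum; ties at or above the cutoff are
    all kept, so cells with several well-supported chains retain them all.
    Chains with missing read counts are treated as unsupported (count 0).
    Adds a ``chains_per_cell`` column counting each cell's surviving chains.
    """
    if not (0 < read_ratio <= 1):
        raise ParameterError(f"read_ratio must be in (0, 1], got {read_ratio}")
    df = table.df.copy()
    reads = df.get("read_count")
    if reads is None:
        reads = pd.Series(0, index=df.index, dtype="Int64")
    reads = pd.to_numeric(reads, errors="coerce").fillna(0).astype(float)
    group_max = reads.groupby([df["cell_id"], df["locus"]]).transform("max")
    keep = reads >= read_ratio * group_max
    # the group maximum itself always survives, including all-zero groups
    keep |= reads == group_max
    out = df[keep].reset_index(drop=True)
    out["chains_per_cell"] = out.groupby("cell_id")["sequence_id"].transform("count")
    return ChainTable(out, table.dialect)
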