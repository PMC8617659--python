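"""Antigen-specific CDR3 search against a repertoire.

Literature-derived CDR3/junction amino-acid sequences of antibodies with
known specificity (e.g. anti-tetanus, anti-diphtheria, anti-pertussis
toxoid) are matched against a repertoire's junctions. Because somatic
hypermutation makes exact matches across individuals unlikely, the search
relaxes identity (default 65%) and allows the subject junction to be
longer or shorter than the query by a flexibility window (default 3
residues). Identity is Levenshtein-based, normalized by the longer
sequence; the length window is applied before any distance is computed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from bcrtrace.clonotype import Clonotype, junction_identity
from bcrtrace.errors import ParameterError, SchemaError, ValidationError
from bcrtrace.io import ChainTable

QUERY_COLUMNS = ["query_id", "antigen", "junction_aa"]


def read_queries(path) -> pd.DataFrame:
    """Read a CSV of antigen-associated junction queries.

    Required columns: query_id, antigen, junction_aa; an optional ``source``
    column carries the literature citation. Query ids must be unique and
    junctions non-empty.
    """
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in QUERY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"query file missing required columns: {missing}")
    if df["query_id"].duplicated().any():
        raise ValidationError("duplicate query_id values in query file")
    if (df["junction_aa"].str.len() == 0).any():
        raise ValidationError("empty junction_aa in query file")
    if "source" not in df.columns:
        df["source"] = ""
    return df


def query_repertoire(
    queries: pd.DataFrame,
    chains: ChainTable,
    min_identity: float = 0.65,
    length_flex: int = 3,
    clone_ids: dict | None = None,
    use: str = "junction_aa",
) -> pd.DataFrame:
    """Match repertoire junctions against antigen-associated queries.

    For each (query, subject) pair whose length difference is within
    ``length_flex``, the Levenshtein identity of the two junctions is
    computed and a hit emitted iff it reaches ``min_identity``. Hits carry
    the subject's clone id (from ``clone_ids``), visit and constant gene
    when available, and are sorted by (query_id, descending identity,
    sequence_id).

    Parameters
    ----------
    min_identity:
        Fraction in (0, 1]; the relaxation accommodating individual-specific
        SHM (the field typically searches at 60-70%).
    length_flex:
        Maximum absolute subject-minus-query length difference (residues).
    use:
        Subject column to compare, ``junction_aa`` (default) or ``junction``
        for a nucleotide-level search.
    """
    if queries is None or len(queries) == 0:
        raise ParameterError("empty query set")
    if not (0 < min_identity <= 1):
        raise ParameterError(f"min_identity must be in (0, 1], got {min_identity}")
    if length_flex < 0:
        raise ParameterError(f"length_flex must be >= 0, got {length_flex}")

    df = chains.df
    subjects = df[df[use].notna()] if use in df.columns else df.iloc[0:0]
    hits = []
    for query in queries.itertuples(index=False):
        q_seq = query.junction_aa
        for subject in subjects.itertuples(index=False):
            s_seq = getattr(subject, use)
            delta = len(s_seq) - len(q_seq)
            if abs(delta) > length_flex:
                continue
            identity = junction_identity(q_seq, s_seq)
            if identity >= min_identity:
                seq_id = subject.sequence_id
                hits.append(
                    {
                        "query_id": query.query_id,
                        "antigen": query.antigen,
                        "sequence_id": seq_id,
                        "identity": identity,
                        "length_delta": delta,
                        "clone_id": clone_ids.get(seq_id) if clone_ids else None,
                        "visit": getattr(subject, "visit", None),
                        "c_call": getattr(subject, "c_call", None),
                    }
                )
    out = pd.DataFrame(
        hits,
        columns=[
            "query_id",
            "antigen",
            "sequence_id",
            "identity",
            "length_delta",
            "clone_id",
            "visit",
            "c_call",
        ],
    )
    return out.sort_values(
        ["query_id", "identity", "sequence_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def summarize_hits(
    hits: pd.DataFrame,
    clonotypes: list[Clonotype] | None = None,
    antigens: list[str] | None = None,
) -> pd.DataFrame:
    """Per-antigen summary of query hits.

    Reports the number of hit BCRs, distinct hit clonotypes, isotype
    fractions among hits, per-visit hit counts and the best identity per
    clonotype. When ``clonotypes`` is given, the total repertoire size of
    the hit clones is reported too (hits often tag only part of a clone).
    Antigens listed in ``antigens`` but without hits get a zero row rather
    than being dropped.
    """
    clone_sizes = {c.clone_id: c.size for c in clonotypes} if clonotypes else {}
    antigens = sorted(set(antigens or []) | set(hits["antigen"].dropna()))
    rows = []
    for antigen in antigens:
        sub = hits[hits["antigen"] == antigen]
        dedup = sub.drop_duplicates("sequence_id")
        c_calls = dedup["c_call"].dropna()
        isotype_fracs = (
            (c_calls.value_counts() / len(c_calls)).round(6).to_dict() if len(c_calls) else {}
        )
        clones = dedup["clone_id"].dropna()
        best_identity = (
            sub.dropna(subset=["clone_id"]).groupby("clone_id")["identity"].max().to_dict()
        )
        rows.append(
            {
                "antigen": antigen,
                "n_hit_bcrs": int(len(dedup)),
                "n_hit_clonotypes": int(clones.nunique()),
                "isotype_fractions": isotype_fracs,
                "per_visit_hits": dedup["visit"].dropna().value_counts().to_dict(),
                "best_identity_per_clone": best_identity,
                "hit_clone_total_bcrs": int(
                    sum(clone_sizes.get(c, 0) for c in set(clones))
                ),
            }
        )
    return pd.DataFrame(rows)
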