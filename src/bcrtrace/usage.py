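"""Longitudinal repertoire usage statistics.

V/J gene(-family) usage per visit, classification of VJ pairs against a
baseline visit (new / expanded / unchanged, mirroring the link colouring of
longitudinal Circos plots), CDR3-length summaries, kappa:lambda light-chain
ratios, and center-anchored junction amino-acid composition tables.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from bcrtrace.clonotype import strip_allele, v_family
from bcrtrace.errors import ParameterError
from bcrtrace.io import ChainTable


def vj_usage(chains: ChainTable, v_level: str = "family", locus: str = "IGH") -> pd.DataFrame:
    """Per-visit counts and frequencies of (V key, J gene) pairs.

    Returns a tidy frame with columns (visit, v_key, j_gene, count,
    frequency); frequencies sum to 1 within each visit. Pairs observed at
    exactly one visit are flagged ``unique_to_visit``.
    """
    if v_level not in ("gene", "family"):
        raise ParameterError(f"v_level must be 'gene' or 'family', got {v_level!r}")
    df = chains.df
    df = df[df["locus"] == locus] if locus else df
    key = df["v_call"].map(strip_allele if v_level == "gene" else v_family)
    out = (
        pd.DataFrame(
            {
                "visit": df["visit"].fillna("unknown") if "visit" in df else "all",
                "v_key": key,
                "j_gene": df["j_call"].map(strip_allele),
            }
        )
        .groupby(["visit", "v_key", "j_gene"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out["frequency"] = out["count"] / out.groupby("visit")["count"].transform("sum")
    pair_visits = out.groupby(["v_key", "j_gene"])["visit"].transform("nunique")
    out["unique_to_visit"] = pair_visits == 1
    return out


def classify_vj_links(
    visit_usage: pd.DataFrame, baseline_visit: str, expansion_factor: float = 2.0
) -> pd.DataFrame:
    """Classify each visit's VJ pairs against a baseline visit.

    A pair absent at baseline is ``new``; one whose frequency reaches
    ``expansion_factor`` times its baseline frequency is ``expanded``; the
    rest are ``unchanged``. Baseline rows themselves are not classified.
    """
    if baseline_visit not in set(visit_usage["visit"]):
        raise ParameterError(f"baseline visit {baseline_visit!r} not present in the usage table")
    base = visit_usage[visit_usage["visit"] == baseline_visit].set_index(["v_key", "j_gene"])[
        "frequency"
    ]
    rows = []
    for _, row in visit_usage[visit_usage["visit"] != baseline_visit].iterrows():
        pair = (row["v_key"], row["j_gene"])
        base_freq = float(base.get(pair, 0.0))
        if base_freq == 0.0:
            cls = "new"
        elif row["frequency"] >= expansion_factor * base_freq:
            cls = "expanded"
        else:
            cls = "unchanged"
        rows.append(
            {
                "visit": row["visit"],
                "v_key": row["v_key"],
                "j_gene": row["j_gene"],
                "frequency": row["frequency"],
                "baseline_frequency": base_freq,
                "link_class": cls,
            }
        )
    return pd.DataFrame(rows)


def _cdr3_lengths(df: pd.DataFrame, trim_junction: bool = True) -> pd.Series:
    """Amino-acid CDR3 lengths; junction minus conserved C/W flanks if needed."""
    if "cdr3_aa" in df.columns and df["cdr3_aa"].notna().any():
        return df["cdr3_aa"].dropna().str.len()
    lengths = df["junction_aa"].dropna().str.len()
    return lengths - 2 if trim_junction else lengths


def cdr3_length_summary(
    chains: ChainTable,
    by: str = "visit",
    clone_ids: dict | None = None,
    locus: str = "IGH",
) -> pd.DataFrame:
    """Per-visit mean/sd and histogram of amino-acid CDR3 lengths.

    With ``clone_ids`` (sequence_id -> clone id) each clonotype contributes
    one representative length (its first member's) per visit group, as when
    length distributions are plotted per clone rather than per cell.
    Returns columns (group, n, mean, sd, histogram) where ``histogram`` is
    a {length: count} dict; ``sd`` is the sample standard deviation and is
    NaN-free: groups of one report sd 0.0 and are flagged ``n=1``.
    """
    df = chains.df
    df = df[df["locus"] == locus] if locus else df
    if clone_ids is not None:
        df = df[df["sequence_id"].isin(clone_ids)]
        df = df.assign(_clone=df["sequence_id"].map(clone_ids)).drop_duplicates("_clone")
    groups = df[by].fillna("unknown") if by in df else pd.Series("all", index=df.index)
    rows = []
    for group_label, sub in df.groupby(groups, observed=True):
        lengths = _cdr3_lengths(sub)
        if lengths.empty:
            continue
        n = len(lengths)
        rows.append(
            {
                "group": group_label,
                "n": n,
                "mean": float(lengths.mean()),
                "sd": float(lengths.std(ddof=1)) if n > 1 else 0.0,
                "histogram": dict(sorted(Counter(lengths).items())),
            }
        )
    return pd.DataFrame(rows)


def light_chain_ratio(chains: ChainTable, by: str = "visit") -> pd.DataFrame:
    """Kappa:lambda chain ratio per visit.

    Reports raw counts, the reduced integer ratio (e.g. ``3:2``) and the
    decimal value; a visit without lambda chains is flagged infinite rather
    than raising.
    """
    df = chains.light()
    groups = df[by].fillna("unknown") if by in df else pd.Series("all", index=df.index)
    rows = []
    for group_label, sub in df.groupby(groups, observed=True):
        igk = int((sub["locus"] == "IGK").sum())
        igl = int((sub["locus"] == "IGL").sum())
        if igl == 0:
            rows.append(
                {
                    "group": group_label,
                    "igk": igk,
                    "igl": igl,
                    "ratio": f"{igk}:0",
                    "decimal": float("inf"),
                    "infinite": True,
                }
            )
            continue
        g = math.gcd(igk, igl)
        rows.append(
            {
                "group": group_label,
                "igk": igk,
                "igl": igl,
                "ratio": f"{igk // g}:{igl // g}",
                "decimal": igk / igl,
                "infinite": False,
            }
        )
    return pd.DataFrame(rows)


def junction_aa_composition(junctions: list[str]) -> pd.DataFrame:
    """Center-anchored per-position residue frequencies of junctions.

    Positions are aligned from both ends toward the middle (IMGT junction
    convention): the first half of each junction counts from the left, the
    second half from the right end of the longest junction, so conserved
    terminal residues (Cys-104, Trp/Phe-118) line up across lengths.
    Returns a positions x residues frequency frame; each row sums to 1 over
    the residues observed at that position.
    """
    junctions = [j for j in junctions if isinstance(j, str) and j]
    if not junctions:
        raise ParameterError("junction_aa_composition requires a non-empty junction list")
    width = max(len(j) for j in junctions)
    counts = np.zeros((width, 26))
    for j in junctions:
        half = (len(j) + 1) // 2
        for i, residue in enumerate(j):
            col = i if i < half else width - (len(j) - i)
            counts[col, ord(residue.upper()) - 65] += 1
    residues = [chr(65 + i) for i in range(26) if counts[:, i].any()]
    table = pd.DataFrame(
        counts[:, [ord(r) - 65 for r in residues]],
        index=pd.RangeIndex(1, width + 1, name="position"),
        columns=residues,
    )
    return table.div(table.sum(axis=1), axis=0)
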