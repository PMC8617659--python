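"""Somatic hypermutation profiling over IMGT regions.

Mutations are substitutions between a chain's IMGT-gapped V-region
alignment and its germline: positions where both strings carry an
unambiguous base (A/C/G/T) and differ. Counts are tallied per region
(FWR1, CDR1, FWR2, CDR2, FWR3) from the region-bound columns of the
input table, substituted codons are classified replacement vs silent by
translation, and heavy/light mutation loads are compared across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bcrtrace.errors import AnnotationError, InsufficientDataError
from bcrtrace.io import REGIONS, ChainTable, translate_nt

_BASES = frozenset("ACGT")


@dataclass
class RegionMutationProfile:
    """Per-region substitution counts for one chain."""

    sequence_id: str
    fwr1: int
    cdr1: int
    fwr2: int
    cdr2: int
    fwr3: int
    outside: int  # substitutions outside the annotated regions
    total_v: int
    replacement: int
    silent: int

    @property
    def region_counts(self) -> dict:
        return {r: getattr(self, r) for r in REGIONS}


def _substituted_positions(germ: str, obs: str) -> list[int]:
    return [
        i
        for i, (g, o) in enumerate(zip(germ.upper(), obs.upper()))
        if g in _BASES and o in _BASES and g != o
    ]


def count_region_mutations(record: pd.Series, frame_offset: int = 0) -> RegionMutationProfile:
    """Profile one chain's substitutions per IMGT region.

    ``record`` is a row of a chain table with ``sequence_alignment``,
    ``germline_alignment`` and the ``fwr1_start`` .. ``fwr3_end`` bound
    columns (0-based half-open, alignment coordinates). Gap and N positions
    never count. Replacement/silent classification uses ``frame_offset`` to
    locate codon 1 in the alignment.
    """
    obs = record.get("sequence_alignment")
    germ = record.get("germline_alignment")
    if not isinstance(obs, str) or not isinstance(germ, str):
        raise AnnotationError(f"{record.get('sequence_id')}: alignments missing")
    bounds = {}
    for region in REGIONS:
        start, end = record.get(f"{region}_start"), record.get(f"{region}_end")
        if pd.isna(start) or pd.isna(end):
            raise AnnotationError(f"{record.get('sequence_id')}: missing {region} bounds")
        bounds[region] = (int(start), int(end))

    positions = _substituted_positions(germ, obs)
    counts = dict.fromkeys(REGIONS, 0)
    outside = 0
    for pos in positions:
        for region, (start, end) in bounds.items():
            if start <= pos < end:
                counts[region] += 1
                break
        else:
            outside += 1

    rs = classify_rs(record, frame_offset)
    return RegionMutationProfile(
        sequence_id=record.get("sequence_id"),
        **counts,
        outside=outside,
        total_v=len(positions),
        replacement=rs["replacement"],
        silent=rs["silent"],
    )


def classify_rs(record: pd.Series, frame_offset: int = 0) -> dict:
    """Classify substituted codons as replacement or silent.

    Each codon containing at least one substitution is translated in both
    the germline and the observed alignment (full codon vs full codon, one
    call per codon); a changed amino acid is a replacement, an unchanged one
    silent. Codons containing gaps or ambiguous bases are excluded.
    """
    obs = record["sequence_alignment"].upper()
    germ = record["germline_alignment"].upper()
    replacement = silent = 0
    for start in range(frame_offset, len(germ) - 2, 3):
        g_codon, o_codon = germ[start : start + 3], obs[start : start + 3]
        if len(g_codon) < 3 or not (set(g_codon) <= _BASES and set(o_codon) <= _BASES):
            continue
        if g_codon == o_codon:
            continue
        if translate_nt(g_codon) == translate_nt(o_codon):
            silent += 1
        else:
            replacement += 1
    return {"replacement": replacement, "silent": silent}


def mutation_table(chains: ChainTable, frame_offset: int = 0) -> pd.DataFrame:
    """Per-sequence mutation profiles for every row with alignments."""
    rows = []
    for _, record in chains.df.iterrows():
        prof = count_region_mutations(record, frame_offset)
        rows.append(
            {
                "sequence_id": prof.sequence_id,
                "cell_id": record.get("cell_id"),
                "locus": record.get("locus"),
                "visit": record.get("visit"),
                **prof.region_counts,
                "outside": prof.outside,
                "total_v": prof.total_v,
                "replacement": prof.replacement,
                "silent": prof.silent,
            }
        )
    return pd.DataFrame(rows)


def heavy_light_correlation(
    profiles: pd.DataFrame, column: str = "total_v", method: str = "pearson"
) -> dict:
    """Correlate heavy- vs light-chain mutation loads across cells.

    ``profiles`` is a :func:`mutation_table` output containing both loci;
    cells with exactly one heavy and one light profile are paired. Returns
    the correlation coefficient and its two-sided p value (t distribution).
    """
    heavy = profiles[profiles["locus"] == "IGH"].drop_duplicates("cell_id", keep=False)
    light = profiles[profiles["locus"].isin(["IGK", "IGL"])].drop_duplicates(
        "cell_id", keep=False
    )
    paired = heavy.merge(light, on="cell_id", suffixes=("_heavy", "_light"))
    if len(paired) < 3:
        raise InsufficientDataError(
            f"need >= 3 cells with paired heavy/light profiles, got {len(paired)}"
        )
    x = paired[f"{column}_heavy"].to_numpy(float)
    y = paired[f"{column}_light"].to_numpy(float)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return {"r": float(r), "p": float(p), "n": len(paired)}


def significance_stars(p: float) -> str:
    """Map a p value to the conventional asterisk label."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_mutation_loads(group_a, group_b) -> dict:
    """Welch two-sample t-test between two mutation-count groups.

    Degenerate input (zero variance in both groups) yields NaN statistics
    with ``degenerate=True`` rather than an exception. Stars: p in
    (0.01, 0.05] -> ``*``, (0.001, 0.01] -> ``**``, <= 0.001 -> ``***``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "p": 1.0, "stars": "", "degenerate": True}
        return {"t": float("nan"), "p": float("nan"), "stars": "", "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "stars": significance_stars(p), "degenerate": False}
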