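"""Class-switch recombination detection and isotype bookkeeping.

CSR replaces the expressed constant gene with one further downstream in the
IGH locus (IGHM -> IGHG/IGHA/IGHE) and is irreversible, which is why the
constant-gene order doubles as a lineage constraint. A clonotype whose
members use two or more distinct constant genes has undergone (at least
one) class switch.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from bcrtrace.clonotype import Clonotype
from bcrtrace.io import ChainTable

#: Human IGH constant-region genes in genomic (switch) order.
ISOTYPE_ORDER = [
    "IGHM",
    "IGHD",
    "IGHG3",
    "IGHG1",
    "IGHA1",
    "IGHG2",
    "IGHG4",
    "IGHE",
    "IGHA2",
]


def isotype_rank(c_call: str, order: list[str] | None = None) -> int:
    """Position of a constant gene in the switch order."""
    order = ISOTYPE_ORDER if order is None else order
    return order.index(c_call)


def isotype_usage(chains: ChainTable, by: str = "visit") -> pd.DataFrame:
    """Per-visit fraction of chains using each constant gene.

    Chains lacking a ``c_call`` are tallied under ``unassigned``; fractions
    are computed over assigned chains only and sum to 1 within each visit.
    Returns a tidy frame with columns (visit, c_call, count, fraction).
    """
    df = chains.df
    group = df[by].fillna("unknown") if by in df else pd.Series("all", index=df.index)
    c_call = df["c_call"].fillna("unassigned") if "c_call" in df else pd.Series(
        "unassigned", index=df.index
    )
    counts = (
        pd.DataFrame({by: group, "c_call": c_call})
        .groupby([by, "c_call"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    assigned = counts[counts["c_call"] != "unassigned"]
    totals = assigned.groupby(by)["count"].transform("sum")
    counts["fraction"] = float("nan")
    counts.loc[assigned.index, "fraction"] = assigned["count"] / totals
    return counts


def detect_csr_clonotypes(
    clonotypes: list[Clonotype], igmd_coexpression: bool = False
) -> dict:
    """Split clonotypes into single- and multi-isotype (CSR) clones.

    A clonotype is a CSR clonotype iff its members use >= 2 distinct
    constant genes (absent calls ignored). Clones with no assigned isotype
    are excluded from both counts. With ``igmd_coexpression=True`` the
    IGHM/IGHD pair is collapsed before counting: naive B cells co-express
    both via alternative splicing, which is not a recombination event.
    """
    per_clone = {}
    single = multi = 0
    for clone in clonotypes:
        isotypes = clone.isotype_set
        if igmd_coexpression:
            isotypes = frozenset("IGHM" if i == "IGHD" else i for i in isotypes)
        per_clone[clone.clone_id] = isotypes
        if len(isotypes) >= 2:
            multi += 1
        elif len(isotypes) == 1:
            single += 1
    return {
        "single_isotype_count": single,
        "multi_isotype_count": multi,
        "per_clone_isotypes": per_clone,
    }


def isotype_cooccurrence(
    clonotypes: list[Clonotype], order: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of clone counts per isotype pair.

    Entry (x, y) counts the clonotypes whose isotype set contains both x and
    y; a clone with k >= 2 isotypes contributes to all C(k, 2) pairs. The
    diagonal is zero.
    """
    order = ISOTYPE_ORDER if order is None else order
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for clone in clonotypes:
        isotypes = sorted(i for i in clone.isotype_set if i in order)
        for x, y in combinations(isotypes, 2):
            mat.loc[x, y] += 1
            mat.loc[y, x] += 1
    return mat
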