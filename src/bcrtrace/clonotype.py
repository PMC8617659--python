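"""Clonotype assignment by V-grouping and Levenshtein CDR3 identity.

B cells are grouped into clonotypes when they share the same V family (or,
optionally, the same V gene), the same J gene, and their heavy-chain CDR3
nucleotide sequences reach a Levenshtein identity threshold (default 80%).
Within each (V key, J gene) group, chains whose pairwise identity meets the
threshold are linked, and clones are the connected components of that graph
(single linkage), so membership is transitive.

Identity between two strings is ``1 - d / max(|a|, |b|)`` with ``d`` the
Levenshtein distance, so comparing a string to its prefix penalizes the
missing suffix.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd
from sklearn.metrics.cluster import pair_confusion_matrix

from bcrtrace.errors import AnnotationError, ParameterError
from bcrtrace.io import ChainTable

_V_FAMILY_RE = re.compile(r"^(IG[HKL]V\d+)")


def v_family(v_call: str) -> str:
    """Extract the locus+family prefix of a V gene call.

    ``"IGHV3-23*04"`` -> ``"IGHV3"``; allele and gene-number suffixes are
    dropped. Raises :class:`AnnotationError` for unparsable calls.
    """
    if not isinstance(v_call, str):
        raise AnnotationError(f"unparsable V call: {v_call!r}")
    m = _V_FAMILY_RE.match(v_call.strip())
    if not m:
        raise AnnotationError(f"unparsable V call: {v_call!r}")
    return m.group(1)


def strip_allele(call: str) -> str:
    """Truncate a gene+allele call to the gene: ``"IGHJ4*02"`` -> ``"IGHJ4"``."""
    return call.split("*")[0].strip()


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming ``a`` into ``b``."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def junction_identity(a: str, b: str) -> float:
    """Levenshtein identity normalized by the longer sequence, in [0, 1]."""
    if not a and not b:
        raise ParameterError("junction_identity undefined for two empty strings")
    return 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))


@dataclass
class Partition:
    """A clonotype partition of heavy-chain sequence ids.

    ``assignment`` maps each sequence_id to a positive integer clone id;
    ids are 1..K in order of decreasing clone size (ties broken by the
    lexicographically smallest member CDR3).
    """

    assignment: dict[str, int]
    grouping_level: str
    identity_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence_id": list(self.assignment), "clone_id": list(self.assignment.values())}
        )

    @property
    def n_clones(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class Clonotype:
    """One clone: its V/J key, members, per-visit sizes and isotype multiset."""

    clone_id: int
    v_family: str
    j_gene: str
    members: set = field(default_factory=set)
    per_visit_sizes: dict = field(default_factory=dict)
    isotypes: Counter = field(default_factory=Counter)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def isotype_set(self) -> frozenset:
        return frozenset(self.isotypes)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def assign_clonotypes(
    chains: ChainTable,
    grouping_level: str = "family",
    identity_threshold: float = 0.8,
) -> Partition:
    """Partition heavy chains into clonotypes.

    Chains are first split by (V key at ``grouping_level``, J gene); within
    each group, chains with CDR3 nucleotide identity >= ``identity_threshold``
    are linked and clones are the connected components (single linkage).

    Parameters
    ----------
    chains:
        A :class:`~bcrtrace.io.ChainTable`; only IGH rows are clustered.
    grouping_level:
        ``"family"`` (default, e.g. IGHV3) or ``"gene"`` (e.g. IGHV3-23).
    identity_threshold:
        Minimum Levenshtein identity between member CDR3s, in (0, 1].
    """
    if grouping_level not in ("gene", "family"):
        raise ParameterError(f"grouping_level must be 'gene' or 'family', got {grouping_level!r}")
    if not (0 < identity_threshold <= 1):
        raise ParameterError(f"identity_threshold must be in (0, 1], got {identity_threshold}")

    heavy = chains.heavy()
    missing = heavy.loc[heavy["cdr3"].isna(), "sequence_id"].tolist() if "cdr3" in heavy else heavy[
        "sequence_id"
    ].tolist()
    if missing:
        raise AnnotationError(f"heavy chains missing cdr3: {missing[:10]}")

    ids = heavy["sequence_id"].tolist()
    cdr3s = heavy["cdr3"].tolist()
    keys = []
    for v_call, j_call in zip(heavy["v_call"], heavy["j_call"]):
        v_key = strip_allele(v_call) if grouping_level == "gene" else v_family(v_call)
        keys.append((v_key, strip_allele(j_call)))

    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)

    uf = _UnionFind(len(ids))
    for members in groups.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = members[ai], members[bi]
                if junction_identity(cdr3s[a], cdr3s[b]) >= identity_threshold:
                    uf.union(a, b)

    components: dict[int, list[int]] = {}
    for i in range(len(ids)):
        components.setdefault(uf.find(i), []).append(i)
    # clone ids by decreasing size, ties by smallest member cdr3
    ordered = sorted(
        components.values(), key=lambda m: (-len(m), min(cdr3s[i] for i in m))
    )
    assignment: dict[str, int] = {}
    for clone_id, members in enumerate(ordered, start=1):
        for i in members:
            assignment[ids[i]] = clone_id
    return Partition(assignment, grouping_level, identity_threshold)


def rand_index(p: Partition, q: Partition, adjusted: bool = False) -> float:
    """Agreement between two clonotype partitions over the same sequence ids.

    The unadjusted Rand index is the fraction of unordered pairs on which
    the partitions agree (co-clustered in both, or separated in both);
    ``adjusted=True`` returns the chance-corrected variant instead.
    """
    if set(p.assignment) != set(q.assignment):
        raise ParameterError("partitions cover different sequence_id sets")
    ids = sorted(p.assignment)
    a = [p.assignment[i] for i in ids]
    b = [q.assignment[i] for i in ids]
    if len(ids) < 2:
        return 1.0
    (tn, fp), (fn, tp) = pair_confusion_matrix(a, b)
    if adjusted:
        from sklearn.metrics import adjusted_rand_score

        return float(adjusted_rand_score(a, b))
    return float((tp + tn) / (tp + tn + fp + fn))


def build_clonotypes(chains: ChainTable, partition: Partition) -> list[Clonotype]:
    """Materialize :class:`Clonotype` objects from a partition.

    Per-visit sizes count members with a known visit; the isotype multiset
    collects assigned ``c_call`` values of member heavy chains.
    """
    heavy = chains.heavy().set_index("sequence_id")
    clones: dict[int, Clonotype] = {}
    for seq_id, clone_id in partition.assignment.items():
        row = heavy.loc[seq_id]
        if clone_id not in clones:
            clones[clone_id] = Clonotype(
                clone_id=clone_id,
                v_family=v_family(row["v_call"]),
                j_gene=strip_allele(row["j_call"]),
            )
        clone = clones[clone_id]
        clone.members.add(seq_id)
        visit = row.get("visit")
        if isinstance(visit, str) and visit:
            clone.per_visit_sizes[visit] = clone.per_visit_sizes.get(visit, 0) + 1
        c_call = row.get("c_call")
        if isinstance(c_call, str) and c_call:
            clone.isotypes[c_call] += 1
    return [clones[k] for k in sorted(clones)]


def clonotype_summary(clones: list[Clonotype]) -> pd.DataFrame:
    """Tidy per-clone summary (size, V family, J gene, visits, isotypes)."""
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "v_family": c.v_family,
                "j_gene": c.j_gene,
                "size": c.size,
                "per_visit_sizes": ";".join(f"{v}:{n}" for v, n in sorted(c.per_visit_sizes.items())),
                "isotypes": ";".join(f"{i}:{n}" for i, n in sorted(c.isotypes.items())),
            }
        )
    return pd.DataFrame(rows)
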