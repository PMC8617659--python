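"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (full DP matrices, all-pairs scans,
exhaustive tree enumeration via Pruefer sequences) and shares no code with
the package under test.
"""

from itertools import combinations, product


def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming edit distance matrix."""
    rows, cols = len(a) + 1, len(b) + 1
    d = [[0] * cols for _ in range(rows)]
    for i in range(rows):
        d[i][0] = i
    for j in range(cols):
        d[0][j] = j
    for i in range(1, rows):
        for j in range(1, cols):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[-1][-1]


def dp_levenshtein_rowwise(a: str, b: str) -> int:
    """Same full DP recurrence, vectorized one row at a time with numpy.

    curr[j] = min(prev[j] + 1, prev[j-1] + cost, curr[j-1] + 1); the
    sequential third term is resolved with the prefix-minimum identity
    curr[j] = min_k<=j (t[k] + (j - k)) where t holds the first two terms.
    Cross-checked against :func:`dp_levenshtein` in the unit tests.
    """
    import numpy as np

    if not a or not b:
        return max(len(a), len(b))
    an = np.frombuffer(a.encode(), dtype=np.uint8)
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    cols = np.arange(1, len(b) + 1)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(an, 1):
        t = np.minimum(prev[1:] + 1, prev[:-1] + (bn != ca))
        t = np.minimum(t, i + cols)  # boundary: curr[0] = i
        curr = np.minimum.accumulate(t - cols) + cols
        prev = np.concatenate(([i], curr))
    return int(prev[-1])


def oracle_identity(a: str, b: str) -> float:
    return 1.0 - dp_levenshtein(a, b) / max(len(a), len(b))


def oracle_identity_fast(a: str, b: str) -> float:
    return 1.0 - dp_levenshtein_rowwise(a, b) / max(len(a), len(b))


def oracle_clonotypes(records, identity_threshold: float):
    """All-pairs transitive-closure clonotyping.

    ``records`` is a list of (sequence_id, group_key, cdr3); returns a
    mapping sequence_id -> frozenset of co-clustered sequence_ids (the
    clone as a set, which is label-free and thus directly comparable).
    """
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(n), 2):
        if records[i][1] != records[j][1]:
            continue
        a, b = records[i][2], records[j][2]
        # edit distance is at least the length difference, so pairs whose
        # best possible identity misses the threshold need no DP
        if 1.0 - abs(len(a) - len(b)) / max(len(a), len(b)) < identity_threshold:
            continue
        if oracle_identity_fast(a, b) >= identity_threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

    clones = {}
    for i in range(n):
        clones.setdefault(find(i), []).append(records[i][0])
    member_sets = {}
    for members in clones.values():
        fs = frozenset(members)
        for m in members:
            member_sets[m] = fs
    return member_sets


def partition_as_sets(assignment: dict) -> set:
    """Label-free view of a partition: the set of member frozensets."""
    clones = {}
    for item, label in assignment.items():
        clones.setdefault(label, set()).add(item)
    return {frozenset(v) for v in clones.values()}


def oracle_rand_index(p: dict, q: dict) -> float:
    """Pairwise agreement fraction by direct enumeration."""
    items = sorted(p)
    agree = total = 0
    for a, b in combinations(items, 2):
        total += 1
        if (p[a] == p[b]) == (q[a] == q[b]):
            agree += 1
    return agree / total if total else 1.0


def min_spanning_tree_weight(n: int, weight) -> int:
    """Minimum spanning-tree weight by exhaustive enumeration.

    Iterates over all labeled trees on n nodes via Pruefer sequences
    (n^(n-2) trees), so only viable for n <= 7. ``weight(i, j)`` gives the
    edge weight between nodes i and j.
    """
    if n == 1:
        return 0
    if n == 2:
        return weight(0, 1)
    best = None
    for seq in product(range(n), repeat=n - 2):
        edges = _pruefer_to_edges(list(seq), n)
        w = sum(weight(i, j) for i, j in edges)
        if best is None or w < best:
            best = w
    return best


def _pruefer_to_edges(seq, n):
    """Standard Pruefer decoding: returns the n-1 edges of the encoded tree."""
    import heapq

    degree = [1] * n
    for s in seq:
        degree[s] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    a, b = sorted(leaves)[:2]
    edges.append((a, b))
    return edges
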