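"""Clonal lineage trees from somatic hypermutation distances.

A clone's lineage is reconstructed from the IMGT-gapped V-region alignments
of its members: identical sequences collapse into one observed node, and the
tree is the minimum-weight spanning tree over {germline} + unique member
sequences under pairwise substitution (Hamming) counts, rooted at the
germline and directed away from it. Two post-processing steps refine the
raw MST:

* :func:`insert_inferred_nodes` adds unobserved intermediate nodes where
  two or more sibling branches share identical mutations (same position,
  same derived base) relative to their parent — evidence of a common
  unsampled ancestor.
* :func:`enforce_switch_order` adds inferred nodes so that constant-gene
  usage along every root-to-leaf path respects the irreversible order of
  class-switch recombination on the IGH locus.

Distances ignore positions where either sequence carries a gap or N, so
only unambiguous substitutions count as SHM.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from bcrtrace.csr import ISOTYPE_ORDER
from bcrtrace.errors import BcrtraceError, ParameterError, ValidationError

_BASES = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Substitution count over a gapped alignment; gap/N positions skipped."""
    return sum(
        1 for x, y in zip(a.upper(), b.upper()) if x in _BASES and y in _BASES and x != y
    )


def mutations(parent: str, child: str) -> frozenset:
    """Set of (position, derived base) substitutions from parent to child."""
    return frozenset(
        (i, y)
        for i, (x, y) in enumerate(zip(parent.upper(), child.upper()))
        if x in _BASES and y in _BASES and x != y
    )


class LineageTree:
    """Rooted lineage tree over unique clone sequences.

    Nodes carry ``kind`` (germline / observed / inferred), ``sequence``
    (gapped DNA), ``size`` (member chains; 0 for germline and inferred
    nodes), ``visit_composition`` and an optional ``isotype``. Each edge
    weight equals the substitution count between its endpoint sequences.
    """

    ROOT = "germline"

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()
        self._n_inferred = sum(
            1 for _, d in self.graph.nodes(data=True) if d.get("kind") == "inferred"
        )

    # -- construction helpers -------------------------------------------------

    def add_node(self, node_id, kind, sequence, size=0, visit_composition=None, isotype=None):
        self.graph.add_node(
            node_id,
            kind=kind,
            sequence=sequence,
            size=int(size),
            visit_composition=dict(visit_composition or {}),
            isotype=isotype,
        )

    def add_edge(self, parent, child):
        w = hamming(self.graph.nodes[parent]["sequence"], self.graph.nodes[child]["sequence"])
        self.graph.add_edge(parent, child, weight=w)

    def new_inferred_id(self) -> str:
        self._n_inferred += 1
        return f"inferred{self._n_inferred}"

    # -- queries --------------------------------------------------------------

    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def observed_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    def children(self, node) -> list:
        return sorted(self.graph.successors(node))

    def parent(self, node):
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def validate(self) -> None:
        g = self.graph
        if self.ROOT not in g:
            raise ValidationError("tree has no germline root")
        if not nx.is_arborescence(g):
            raise ValidationError("tree is not a rooted arborescence")
        for u, v, d in g.edges(data=True):
            expect = hamming(g.nodes[u]["sequence"], g.nodes[v]["sequence"])
            if d["weight"] != expect:
                raise ValidationError(f"edge {u}->{v} weight {d['weight']} != {expect}")


def build_lineage(members: pd.DataFrame, germline: str) -> LineageTree:
    """Build the rooted MST lineage of one clone.

    Parameters
    ----------
    members:
        Rows of a chain table belonging to one clone, each with a
        ``sequence_alignment`` of the same length as ``germline``
        (``visit`` and ``c_call`` columns contribute node annotations).
    germline:
        IMGT-gapped germline V sequence; becomes the root node.

    Identical member sequences collapse into one observed node whose size is
    the member count. MST edge ties are broken deterministically: smaller
    weight first, then fewer germline differences of the downstream node,
    then lexicographic sequence order.
    """
    germline = germline.upper()
    for _, row in members.iterrows():
        aln = row.get("sequence_alignment")
        if not isinstance(aln, str) or len(aln) != len(germline):
            raise ValidationError(
                f"{row.get('sequence_id')}: sequence_alignment missing or length != germline"
            )

    # collapse identical sequences
    by_seq: dict[str, dict] = {}
    for _, row in members.iterrows():
        seq = row["sequence_alignment"].upper()
        info = by_seq.setdefault(seq, {"size": 0, "visits": {}, "isotypes": {}})
        info["size"] += 1
        visit = row.get("visit")
        if isinstance(visit, str) and visit:
            info["visits"][visit] = info["visits"].get(visit, 0) + 1
        c_call = row.get("c_call")
        if isinstance(c_call, str) and c_call:
            info["isotypes"][c_call] = info["isotypes"].get(c_call, 0) + 1

    uniques = sorted(by_seq, key=lambda s: (hamming(s, germline), s))
    tree = LineageTree()
    tree.add_node(LineageTree.ROOT, "germline", germline)
    seq_of = {LineageTree.ROOT: germline}
    for idx, seq in enumerate(uniques, start=1):
        info = by_seq[seq]
        isotype = None
        if info["isotypes"]:
            # majority isotype; ties resolved by earliest switch order
            def _key(item):
                gene, count = item
                rank = ISOTYPE_ORDER.index(gene) if gene in ISOTYPE_ORDER else len(ISOTYPE_ORDER)
                return (-count, rank, gene)

            isotype = sorted(info["isotypes"].items(), key=_key)[0][0]
        node_id = f"seq{idx}"
        tree.add_node(node_id, "observed", seq, info["size"], info["visits"], isotype)
        seq_of[node_id] = seq

    # Kruskal over {germline} + unique-sequence nodes, deterministic tie-breaks
    vertices = list(seq_of)
    dist_g = {n: hamming(seq_of[n], germline) for n in vertices}
    edges = []
    for i in range(len(vertices)):
        for j in range(i + 1, len(vertices)):
            a, b = vertices[i], vertices[j]
            # the downstream ("child") endpoint is the one farther from germline
            child, other = (a, b) if (dist_g[a], seq_of[a], a) > (dist_g[b], seq_of[b], b) else (b, a)
            edges.append((hamming(seq_of[a], seq_of[b]), dist_g[child], seq_of[child], child, other))
    edges.sort()

    parent_uf = {v: v for v in vertices}

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    chosen = []
    for w, _, _, child, other in edges:
        ra, rb = find(child), find(other)
        if ra != rb:
            parent_uf[ra] = rb
            chosen.append((child, other))

    undirected = nx.Graph()
    undirected.add_nodes_from(vertices)
    undirected.add_edges_from(chosen)
    for parent_node, child_node in nx.bfs_edges(undirected, LineageTree.ROOT):
        tree.add_edge(parent_node, child_node)
    return tree


def insert_inferred_nodes(tree: LineageTree) -> LineageTree:
    """Insert unsampled intermediate nodes implied by shared mutations.

    Whenever >= 2 children of one node acquired an identical mutation (same
    alignment position, same derived base) relative to that node, the shared
    mutations are placed on a single inferred intermediate and the children
    re-attached beneath it. The candidate group with the largest shared
    mutation set is resolved first; total tree weight never increases and
    observed nodes are untouched.
    """
    g = tree.graph
    work = [LineageTree.ROOT]
    while work:
        node = work.pop()
        children = tree.children(node)
        if len(children) < 2:
            work.extend(children)
            continue
        parent_seq = g.nodes[node]["sequence"]
        muts = {c: mutations(parent_seq, g.nodes[c]["sequence"]) for c in children}

        # candidate groups: children sharing at least one mutation
        groups = {}
        for m in set().union(*muts.values()):
            grp = frozenset(c for c in children if m in muts[c])
            if len(grp) >= 2:
                groups[grp] = frozenset.intersection(*(muts[c] for c in grp))
        if not groups:
            work.extend(children)
            continue
        grp, shared = min(
            groups.items(), key=lambda kv: (-len(kv[1]), -len(kv[0]), sorted(kv[1]))
        )
        seq = list(parent_seq)
        for pos, base in shared:
            seq[pos] = base
        inferred = tree.new_inferred_id()
        tree.add_node(inferred, "inferred", "".join(seq))
        tree.add_edge(node, inferred)
        for c in sorted(grp):
            g.remove_edge(node, c)
            tree.add_edge(inferred, c)
        work.append(node)  # re-examine: more groups may remain
    return tree


def enforce_switch_order(tree: LineageTree, order: list[str] | None = None) -> LineageTree:
    """Make constant-gene usage non-decreasing along every root-to-leaf path.

    Class switching only moves downstream on the IGH locus, so an observed
    node whose isotype precedes an ancestor's is evidence of an unsampled
    pre-switch intermediate: an inferred node carrying the descendant's
    sequence and its earlier isotype is inserted above the offending
    ancestor, and the descendant re-attached beneath it (zero-weight edge).
    Iterated until every path is order-consistent. Node sizes never change.
    """
    order = ISOTYPE_ORDER if order is None else order
    g = tree.graph
    for _, d in g.nodes(data=True):
        iso = d.get("isotype")
        if iso is not None and iso not in order:
            raise ParameterError(f"isotype {iso!r} not in the configured switch order")

    def rank(node):
        iso = g.nodes[node].get("isotype")
        return order.index(iso) if iso is not None else None

    while True:
        violation = None  # (first too-high ancestor, violating descendant)
        stack = [(LineageTree.ROOT, [])]  # node, ancestor path of ranked nodes
        while stack and violation is None:
            node, ranked_path = stack.pop()
            r = rank(node)
            if r is not None:
                for anc, r_anc in ranked_path:
                    if r_anc > r:
                        violation = (anc, node)
                        break
                new_path = ranked_path + [(node, r)]
            else:
                new_path = ranked_path
            if violation:
                break
            for child in tree.children(node):
                stack.append((child, new_path))
        if violation is None:
            return tree

        anc, desc = violation
        grand = tree.parent(anc)
        inferred = tree.new_inferred_id()
        desc_data = g.nodes[desc]
        tree.add_node(inferred, "inferred", desc_data["sequence"], isotype=desc_data["isotype"])
        g.remove_edge(grand, anc)
        tree.add_edge(grand, inferred)
        tree.add_edge(inferred, anc)
        desc_parent = tree.parent(desc)
        g.remove_edge(desc_parent, desc)
        tree.add_edge(inferred, desc)


def export_tree(tree: LineageTree, fmt: str, path) -> None:
    """Serialize a lineage tree losslessly to graphml, dot or json."""
    path = Path(path)
    g = tree.graph
    if fmt == "json":
        payload = {
            "root": LineageTree.ROOT,
            "nodes": [
                {
                    "id": n,
                    "kind": d["kind"],
                    "sequence": d["sequence"],
                    "size": d["size"],
                    "visit_composition": d.get("visit_composition", {}),
                    "isotype": d.get("isotype"),
                }
                for n, d in sorted(g.nodes(data=True))
            ],
            "edges": [
                {"parent": u, "child": v, "weight": d["weight"]}
                for u, v, d in sorted(g.edges(data=True))
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "graphml":
        out = nx.DiGraph()
        for n, d in g.nodes(data=True):
            out.add_node(
                n,
                kind=d["kind"],
                sequence=d["sequence"],
                size=d["size"],
                visit_composition=json.dumps(d.get("visit_composition", {}), sort_keys=True),
                isotype=d.get("isotype") or "",
            )
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, weight=int(d["weight"]))
        nx.write_graphml(out, path)
    elif fmt == "dot":
        lines = ["digraph lineage {"]
        for n, d in sorted(g.nodes(data=True)):
            label = f"{n} ({d['kind']}, n={d['size']})"
            lines.append(f'  "{n}" [label="{label}"];')
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f'  "{u}" -> "{v}" [label="{d["weight"]}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ParameterError(f"unknown export format: {fmt!r}")


def read_tree(path, fmt: str = "json") -> LineageTree:
    """Load a tree written by :func:`export_tree` (json or graphml)."""
    path = Path(path)
    tree = LineageTree()
    if fmt == "json":
        payload = json.loads(path.read_text())
        for nd in payload["nodes"]:
            tree.add_node(
                nd["id"], nd["kind"], nd["sequence"], nd["size"], nd["visit_composition"], nd["isotype"]
            )
        for ed in payload["edges"]:
            tree.graph.add_edge(ed["parent"], ed["child"], weight=ed["weight"])
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            tree.add_node(
                n,
                d["kind"],
                d["sequence"],
                int(d["size"]),
                json.loads(d["visit_composition"]),
                d["isotype"] or None,
            )
        for u, v, d in g.edges(data=True):
            tree.graph.add_edge(u, v, weight=int(d["weight"]))
    else:
        raise ParameterError(f"unknown format: {fmt!r}")
    return tree
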