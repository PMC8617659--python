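"""Lineage trees: MST construction, inferred nodes, switch-order repair."""

import random

import pandas as pd
import pytest

from bcrtrace.csr import ISOTYPE_ORDER
from bcrtrace.errors import ParameterError, ValidationError
from bcrtrace.lineage import (
    LineageTree,
    build_lineage,
    enforce_switch_order,
    export_tree,
    hamming,
    insert_inferred_nodes,
    mutations,
    read_tree,
)
from oracles import min_spanning_tree_weight

GERMLINE = "ACGT" * 10  # 40 nt


def members_frame(seqs, visits=None, isotypes=None):
    visits = visits or [None] * len(seqs)
    isotypes = isotypes or [None] * len(seqs)
    return pd.DataFrame(
        {
            "sequence_id": [f"m{i}" for i in range(len(seqs))],
            "sequence_alignment": seqs,
            "visit": visits,
            "c_call": isotypes,
        }
    )


def mutate(seq, *changes):
    s = list(seq)
    for pos, base in changes:
        s[pos] = base
    return "".join(s)


class TestHamming:
    def test_gaps_and_n_ignored(self):
        assert hamming("AC-TN", "AGGTC") == 1  # only pos 1 counts
        assert hamming("ACGT", "ACGT") == 0

    def test_mutation_set(self):
        assert mutations("ACGT", "AGGA") == {(1, "G"), (3, "A")}


class TestBuildLineage:
    def test_star_beats_chain(self):
        # two seqs, each 1 away from germline at different positions, 2 apart
        a = mutate(GERMLINE, (0, "G"))
        b = mutate(GERMLINE, (5, "A"))
        tree = build_lineage(members_frame([a, b]), GERMLINE)
        tree.validate()
        assert tree.total_weight() == 2
        assert set(tree.children(LineageTree.ROOT)) == {"seq1", "seq2"}

    def test_identical_members_collapse(self):
        seq = mutate(GERMLINE, (3, "A"))
        frame = members_frame([seq] * 58, visits=["d5"] * 34 + [None] * 24)
        tree = build_lineage(frame, GERMLINE)
        observed = tree.observed_nodes()
        assert len(observed) == 1
        node = tree.graph.nodes[observed[0]]
        assert node["size"] == 58
        assert node["visit_composition"] == {"d5": 34}

    def test_germline_identical_clone(self):
        tree = build_lineage(members_frame([GERMLINE, GERMLINE]), GERMLINE)
        tree.validate()
        observed = tree.observed_nodes()
        assert len(observed) == 1
        assert tree.graph.edges[LineageTree.ROOT, observed[0]]["weight"] == 0

    def test_alignment_length_mismatch_names_sequence(self):
        frame = members_frame([GERMLINE[:-1]])
        with pytest.raises(ValidationError, match="m0"):
            build_lineage(frame, GERMLINE)

    def test_deterministic(self):
        rng = random.Random(5)
        seqs = [
            mutate(GERMLINE, *[(rng.randrange(40), rng.choice("ACGT")) for _ in range(3)])
            for _ in range(6)
        ]
        t1 = build_lineage(members_frame(seqs), GERMLINE)
        t2 = build_lineage(members_frame(seqs), GERMLINE)
        assert sorted(t1.graph.edges(data=True)) == sorted(t2.graph.edges(data=True))

    @pytest.mark.parametrize("seed", range(10))
    def test_mst_weight_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n_unique = rng.randint(1, 6)
        seqs = []
        while len(set(seqs)) < n_unique:
            seqs.append(
                mutate(GERMLINE, *[(rng.randrange(40), rng.choice("ACGT")) for _ in range(rng.randint(1, 5))])
            )
        seqs = sorted(set(seqs))
        tree = build_lineage(members_frame(seqs), GERMLINE)
        tree.validate()
        vertices = [GERMLINE] + seqs
        oracle = min_spanning_tree_weight(
            len(vertices), lambda i, j: hamming(vertices[i], vertices[j])
        )
        assert tree.total_weight() == oracle

    def test_mst_weight_at_most_star_weight(self):
        rng = random.Random(99)
        for _ in range(10):
            seqs = [
                mutate(GERMLINE, *[(rng.randrange(40), rng.choice("ACGT")) for _ in range(rng.randint(1, 6))])
                for _ in range(rng.randint(2, 8))
            ]
            tree = build_lineage(members_frame(seqs), GERMLINE)
            star = sum(hamming(s, GERMLINE) for s in set(seqs))
            assert tree.total_weight() <= star


class TestInferredNodes:
    def test_shared_mutation_extracted(self):
        # children differ from germline at {5:A, 9:T} and {5:A, 12:C}
        a = mutate(GERMLINE, (5, "A"), (9, "T"))
        b = mutate(GERMLINE, (5, "A"), (12, "C"))
        tree = build_lineage(members_frame([a, b]), GERMLINE)
        assert tree.total_weight() == 4
        tree = insert_inferred_nodes(tree)
        tree.validate()
        assert tree.total_weight() == 3
        inferred = [n for n, d in tree.graph.nodes(data=True) if d["kind"] == "inferred"]
        assert len(inferred) == 1
        assert mutations(GERMLINE, tree.graph.nodes[inferred[0]]["sequence"]) == {(5, "A")}

    def test_disjoint_mutations_unchanged(self):
        a = mutate(GERMLINE, (1, "G"))
        b = mutate(GERMLINE, (7, "C"))
        tree = build_lineage(members_frame([a, b]), GERMLINE)
        before = sorted(tree.graph.edges)
        tree = insert_inferred_nodes(tree)
        assert sorted(tree.graph.edges) == before

    def test_chain_tree_unchanged(self):
        a = mutate(GERMLINE, (1, "G"))
        b = mutate(GERMLINE, (1, "G"), (7, "C"))
        tree = build_lineage(members_frame([a, b]), GERMLINE)
        before = sorted(tree.graph.edges)
        assert insert_inferred_nodes(tree).graph.number_of_nodes() == 3
        assert sorted(tree.graph.edges) == before

    @pytest.mark.parametrize("seed", range(8))
    def test_never_increases_weight_or_alters_observed(self, seed):
        rng = random.Random(seed)
        seqs = [
            mutate(GERMLINE, *[(rng.randrange(40), rng.choice("ACGT")) for _ in range(rng.randint(1, 6))])
            for _ in range(rng.randint(3, 10))
        ]
        tree = build_lineage(members_frame(seqs), GERMLINE)
        before_weight = tree.total_weight()
        before_observed = sorted(
            (d["sequence"], d["size"]) for _, d in tree.graph.nodes(data=True) if d["kind"] == "observed"
        )
        tree = insert_inferred_nodes(tree)
        tree.validate()
        after_observed = sorted(
            (d["sequence"], d["size"]) for _, d in tree.graph.nodes(data=True) if d["kind"] == "observed"
        )
        assert tree.total_weight() <= before_weight
        assert after_observed == before_observed


def path_isotypes(tree):
    """Isotype sequences along every root-to-leaf path."""
    paths = []
    stack = [(LineageTree.ROOT, [])]
    while stack:
        node, acc = stack.pop()
        iso = tree.graph.nodes[node].get("isotype")
        acc = acc + ([iso] if iso else [])
        children = tree.children(node)
        if not children:
            paths.append(acc)
        stack.extend((c, acc) for c in children)
    return paths


class TestSwitchOrder:
    def test_backward_switch_gets_inferred_ancestor(self):
        parent = mutate(GERMLINE, (3, "A"))
        child = mutate(GERMLINE, (3, "A"), (8, "T"))
        tree = build_lineage(
            members_frame([parent, child], isotypes=["IGHG1", "IGHM"]), GERMLINE
        )
        tree = enforce_switch_order(tree)
        tree.validate()
        ranks = [[ISOTYPE_ORDER.index(i) for i in p] for p in path_isotypes(tree)]
        assert all(r == sorted(r) for r in ranks)
        inferred = [n for n, d in tree.graph.nodes(data=True) if d["kind"] == "inferred"]
        assert any(tree.graph.nodes[n]["isotype"] == "IGHM" for n in inferred)

    def test_ordered_path_unchanged(self):
        seqs = [mutate(GERMLINE, (3, "A")), mutate(GERMLINE, (3, "A"), (8, "T"))]
        tree = build_lineage(members_frame(seqs, isotypes=["IGHM", "IGHG1"]), GERMLINE)
        before = sorted(tree.graph.edges)
        tree = enforce_switch_order(tree)
        assert sorted(tree.graph.edges) == before

    def test_uniform_isotype_unchanged(self):
        seqs = [mutate(GERMLINE, (i, "A")) for i in (3, 8, 15)]
        tree = build_lineage(members_frame(seqs, isotypes=["IGHG1"] * 3), GERMLINE)
        before = sorted(tree.graph.edges)
        assert sorted(enforce_switch_order(tree).graph.edges) == before

    def test_unknown_isotype_rejected(self):
        tree = build_lineage(members_frame([mutate(GERMLINE, (3, "A"))], isotypes=["IGHZ9"]), GERMLINE)
        with pytest.raises(ParameterError):
            enforce_switch_order(tree)

    @pytest.mark.parametrize("seed", range(8))
    def test_all_paths_sorted_and_sizes_preserved(self, seed):
        rng = random.Random(seed)
        seqs, isotypes = [], []
        for _ in range(rng.randint(3, 12)):
            seqs.append(
                mutate(GERMLINE, *[(rng.randrange(40), rng.choice("ACGT")) for _ in range(rng.randint(1, 5))])
            )
            isotypes.append(rng.choice(ISOTYPE_ORDER))
        tree = build_lineage(members_frame(seqs, isotypes=isotypes), GERMLINE)
        total_before = sum(d["size"] for _, d in tree.graph.nodes(data=True))
        tree = enforce_switch_order(insert_inferred_nodes(tree))
        tree.validate()
        assert sum(d["size"] for _, d in tree.graph.nodes(data=True)) == total_before == len(seqs)
        for path in path_isotypes(tree):
            ranks = [ISOTYPE_ORDER.index(i) for i in path]
            assert ranks == sorted(ranks)


class TestExport:
    @pytest.fixture()
    def tree(self):
        seqs = [mutate(GERMLINE, (3, "A")), mutate(GERMLINE, (3, "A"), (8, "T"))]
        return build_lineage(
            members_frame(seqs, visits=["d5", "d7"], isotypes=["IGHM", "IGHG1"]), GERMLINE
        )

    def test_json_round_trip(self, tree, tmp_path):
        path = tmp_path / "tree.json"
        export_tree(tree, "json", path)
        again = read_tree(path, "json")
        assert sorted(tree.graph.nodes(data=True)) == sorted(again.graph.nodes(data=True))
        assert sorted(tree.graph.edges(data=True)) == sorted(again.graph.edges(data=True))

    def test_graphml_preserves_sizes(self, tree, tmp_path):
        path = tmp_path / "tree.graphml"
        export_tree(tree, "graphml", path)
        again = read_tree(path, "graphml")
        sizes = {n: d["size"] for n, d in tree.graph.nodes(data=True)}
        assert {n: d["size"] for n, d in again.graph.nodes(data=True)} == sizes
        visits = {n: d["visit_composition"] for n, d in again.graph.nodes(data=True)}
        assert visits["seq1"] == {"d5": 1}

    def test_dot_one_line_per_edge(self, tree, tmp_path):
        path = tmp_path / "tree.dot"
        export_tree(tree, "dot", path)
        text = path.read_text()
        assert text.count("->") == tree.graph.number_of_edges()

    def test_unknown_format_rejected(self, tree, tmp_path):
        with pytest.raises(ParameterError):
            export_tree(tree, "newick", tmp_path / "x")
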