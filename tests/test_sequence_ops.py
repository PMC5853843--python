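import io as std_io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.tree import TreeNode

from carbshell import sequence_ops as so
from carbshell import synthetic_data as sd
from carbshell.io_formats import ProteinRecord


def recs(seqs, prefix="s"):
    return [ProteinRecord(f"{prefix}{i}", "g", s) for i, s in enumerate(seqs)]


class TestPairwiseIdentity:
    def test_identical(self):
        assert so.pairwise_identity("MSIAVG", "MSIAVG") == 1.0

    def test_three_quarters(self):
        assert so.pairwise_identity("AAAA", "AAAT") == 0.75

    def test_gap_positions_excluded(self):
        # only 2 comparable positions, both matching
        assert so.pairwise_identity("AA--", "AAT-") == 1.0

    def test_no_comparable_positions(self):
        with pytest.raises(ValueError):
            so.pairwise_identity("A--", "-AA"[:3])

    def test_unequal_length(self):
        with pytest.raises(ValueError):
            so.pairwise_identity("AA", "AAA")


class TestReduceRedundancy:
    def test_identical_pair_keeps_first(self):
        records = recs(["MSIAVG", "MSIAVG"])
        kept = so.reduce_redundancy(records)
        assert [r.protein_id for r in kept] == ["s0"]

    def test_all_distinct_kept(self):
        records = recs(["AAAA", "AATT", "TTTT"])
        assert len(so.reduce_redundancy(records, threshold=0.99)) == 3

    def test_greedy_chain_not_clique(self):
        # A~B and B~C above threshold, A~C below: greedy keeps A and C
        a = "A" * 100
        b = "A" * 99 + "C"
        c = "A" * 98 + "CC"
        kept = so.reduce_redundancy(recs([a, b, c]), threshold=0.985)
        assert [r.protein_id for r in kept] == ["s0", "s2"]

    def test_kept_set_property(self):
        rng = np.random.default_rng(4)
        pool = recs(
            [
                "".join(rng.choice(list("ACDE"), size=30))
                for _ in range(25)
            ]
        )
        kept = so.reduce_redundancy(pool, threshold=0.9)
        for i, a in enumerate(kept):
            for b in kept[:i]:
                assert so.pairwise_identity(a.sequence, b.sequence) <= 0.9


class TestTrimColumns:
    def test_gap_free_unchanged(self):
        records = recs(["MSIAVG", "MSIAVG", "MSIATG"])
        trimmed, kept = so.trim_columns(records)
        assert kept == list(range(6))
        assert [r.sequence for r in trimmed] == [r.sequence for r in records]

    def test_sixty_percent_gap_column_dropped(self):
        records = recs(["A-A", "A-A", "A-A", "AGA", "ACA"])
        trimmed, kept = so.trim_columns(records, max_gap_fraction=0.5)
        assert kept == [0, 2]
        assert trimmed[0].sequence == "AA"

    def test_idempotent(self):
        records = recs(["A-A", "A-A", "A-A", "AGA", "ACA"])
        once, _ = so.trim_columns(records)
        twice, kept = so.trim_columns(once)
        assert [r.sequence for r in twice] == [r.sequence for r in once]
        assert kept == list(range(2))

    def test_all_columns_dropped(self):
        with pytest.raises(ValueError):
            so.trim_columns(recs(["-", "-", "-"]))


def tree_distance_matrix():
    # additive distances from ((A:1,B:2):1,(C:3,D:1))
    labels = list("ABCD")
    d = {"AB": 3, "AC": 5, "AD": 3, "BC": 6, "BD": 4, "CD": 4}
    m = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = d[a + b]
    return so.DistanceMatrix(labels=labels, matrix=m)


def newick_bipartitions(newick):
    """Non-trivial splits, each canonicalized to the side without the first tip."""
    tree = TreeNode.read(std_io.StringIO(newick))
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    splits = set()
    for node in tree.traverse(include_self=False):
        if not node.is_tip():
            part = frozenset(t.name for t in node.tips())
            side = tips - part if ref in part else part
            if 2 <= len(side) <= len(tips) - 2:
                splits.add(side)
    return splits


class TestNjTree:
    def test_additive_four_taxa_recovered_exactly(self):
        newick = so.nj_tree(tree_distance_matrix())
        # single non-trivial split AB|CD (canonical side omits A)
        assert newick_bipartitions(newick) == {frozenset("CD")}
        tree = TreeNode.read(std_io.StringIO(newick))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})

    def test_three_taxa_star(self):
        dm = so.DistanceMatrix(
            labels=list("ABC"),
            matrix=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float),
        )
        tree = TreeNode.read(std_io.StringIO(so.nj_tree(dm)))
        assert {t.name for t in tree.tips()} == set("ABC")

    def test_ultrametric_degenerate_zero_internal(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        dm = so.DistanceMatrix(labels=list("ABCD"), matrix=m)
        tree = TreeNode.read(std_io.StringIO(so.nj_tree(dm)))
        internal = [
            n.length for n in tree.traverse(include_self=False) if not n.is_tip()
        ]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_too_few_taxa(self):
        dm = so.DistanceMatrix(labels=["A", "B"], matrix=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            so.nj_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            so.DistanceMatrix(labels=["A", "B"], matrix=np.array([[0, 1], [2, 0]], float))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=8))
    def test_additive_matrices_recover_topology(self, seed, n_taxa):
        # build a random binary tree, read its additive distances, re-run NJ
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        nodes = [TreeNode(name=l) for l in labels]
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]
            for x in (a, b):
                x.length = float(rng.uniform(0.5, 2.0))
            parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
            nodes.append(parent)
        for x in nodes:
            if x.length is None:
                x.length = float(rng.uniform(0.5, 2.0))
        root = TreeNode(children=nodes)
        tip_map = {t.name: t for t in root.tips()}
        m = np.zeros((n_taxa, n_taxa))
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                d = tip_map[labels[i]].distance(tip_map[labels[j]])
                m[i, j] = m[j, i] = d
        dm = so.DistanceMatrix(labels=labels, matrix=m)
        assert newick_bipartitions(so.nj_tree(dm)) == newick_bipartitions(str(root))

    def test_distance_matrix_tsv_round_trip(self, tmp_path):
        dm = tree_distance_matrix()
        path = tmp_path / "dm.tsv"
        dm.to_tsv(str(path))
        again = so.DistanceMatrix.from_tsv(str(path))
        assert again.labels == dm.labels
        assert np.allclose(again.matrix, dm.matrix)


class TestClassMonophyly:
    def test_clean_split(self):
        result = so.class_monophyly(
            "((a1:1,a2:1):1,(b1:1,b2:1):1);", {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        )
        assert result == {"a": (True, 2), "b": (True, 2)}

    def test_interleaved_not_monophyletic(self):
        result = so.class_monophyly(
            "((a1:1,b1:1):1,(a2:1,b2:1):1);", {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        )
        assert result["a"] == (False, 2)
        assert result["b"] == (False, 2)

    def test_singleton_trivially_monophyletic(self):
        result = so.class_monophyly(
            "((a1:1,a2:1):1,c:1);", {"a1": "a", "a2": "a", "c": "c"}
        )
        assert result["c"] == (True, 1)

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            so.class_monophyly("((a:1,b:1):1,c:1);", {"a": "x", "b": "x"})

    def test_synthetic_classes_cluster(self):
        records, labels = sd.generate_sequences(
            10,
            substitution_rate=0.05,
            classes=("CcmK3", "CcmK4", "CcmK5", "CcmK6", "EutM"),
            seed=19,
        )
        # classes differ slightly in archetype length: pad with terminal gaps
        width = max(len(r.sequence) for r in records)
        records = [
            ProteinRecord(r.protein_id, r.genome_id, r.sequence.ljust(width, "-"))
            for r in records
        ]
        dm = so.p_distance_matrix(records)
        result = so.class_monophyly(so.nj_tree(dm), labels)
        n_mono = sum(1 for mono, _ in result.values() if mono)
        assert n_mono >= 4


class TestColumnInformation:
    def test_fully_conserved_no_pseudocount(self):
        profile = so.column_information(recs(["A", "A", "A"]), pseudocount=0.0)
        assert profile.information[0] == pytest.approx(np.log2(20), abs=1e-9)

    def test_background_column_zero_bits(self):
        # 20 sequences, one of each residue, no pseudocount: matches uniform bg
        seqs = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        profile = so.column_information(recs(seqs), pseudocount=0.0)
        assert profile.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_heights_sum_to_information(self):
        records = recs(["AC", "AC", "AG", "TC"])
        profile = so.column_information(records)
        assert np.allclose(profile.heights.sum(axis=1), profile.information, atol=1e-9)

    def test_non_negative_and_column_order_invariant(self):
        records = recs(["ACG", "ACG", "AGG"])
        fwd = so.column_information(records)
        rev = so.column_information(recs([s[::-1] for s in ["ACG", "ACG", "AGG"]]))
        assert (fwd.information >= 0).all()
        assert np.allclose(fwd.information, rev.information[::-1])

    def test_dilution_decreases_information(self):
        rng = np.random.default_rng(9)
        conserved = ["A"] * 20
        diluted = ["A"] * 10 + [
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=10)
        ]
        ic_c = so.column_information(recs(conserved)).information[0]
        ic_d = so.column_information(recs(diluted)).information[0]
        assert ic_d < ic_c

    def test_empty_alignment(self):
        with pytest.raises(ValueError):
            so.column_information([])
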