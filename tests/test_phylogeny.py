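"""Masking, distances, NJ, bootstrap consensus, subfamily assignment."""

import numpy as np
import pytest

from grasfam.alignment import MultipleAlignment, progressive_msa
from grasfam.phylogeny import (
    PhyloParams,
    Tree,
    TreeNode,
    assign_subfamilies,
    bootstrap_consensus,
    distance_matrix,
    jtt_correct,
    mask_columns,
    nj_tree,
)

from _oracles import random_additive_tree, tree_path_lengths


def _msa(rows):
    return MultipleAlignment(rows=list(rows))


class TestMaskColumns:
    def test_exact_threshold_column_kept(self):
        # 20 rows, one gap: coverage exactly 0.95 -> "less than" is strict
        rows = [(f"r{i}", "AC") for i in range(19)] + [("r19", "-C")]
        masked = mask_columns(_msa(rows), 0.95)
        assert masked.length == 2

    def test_below_threshold_column_removed(self):
        rows = [(f"r{i}", "AC") for i in range(18)] + [
            ("r18", "-C"),
            ("r19", "-C"),
        ]
        masked = mask_columns(_msa(rows), 0.95)  # coverage 0.90
        assert masked.length == 1
        assert masked.rows[0][1] == "C"

    def test_all_gap_column_removed(self):
        rows = [("a", "A-C"), ("b", "A-C")]
        assert mask_columns(_msa(rows), 0.95).length == 2

    def test_gap_free_msa_unchanged(self):
        rows = [("a", "ACDE"), ("b", "ACDF")]
        assert mask_columns(_msa(rows), 0.95).rows == rows

    def test_everything_masked_is_an_error(self):
        rows = [("a", "A-"), ("b", "-A")]
        with pytest.raises(ValueError, match="unusable"):
            mask_columns(_msa(rows), 0.95)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        labels, D = distance_matrix(_msa([("a", "ACDE"), ("b", "ACDE")]))
        assert D[0, 1] == 0.0

    def test_p_distance_counts_mismatches_over_ungapped_columns(self):
        rows = [("a", "AAAAAAAAAA"), ("b", "AAACCCAAAA".replace("C", "R", 3))]
        labels, D = distance_matrix(_msa(rows), model="p_distance")
        assert D[0, 1] == pytest.approx(0.3)

    def test_gapped_columns_excluded_from_comparison(self):
        rows = [("a", "AC-E"), ("b", "AC-E")]
        _, D = distance_matrix(_msa(rows), model="p_distance")
        assert D[0, 1] == 0.0

    def test_jtt_correction_dominates_p_distance(self):
        for p in np.linspace(0.0, 0.8, 30):
            assert jtt_correct(p) >= p

    def test_no_comparable_columns_names_pair(self):
        rows = [("left", "A-"), ("right", "-A")]
        with pytest.raises(ValueError, match="left"):
            distance_matrix(_msa(rows))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(["A", "B", "C"], D)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_eight_taxon_recovery(self):
        rng = np.random.default_rng(42)
        labels, D, splits = random_additive_tree(rng, 8)
        tree = nj_tree(labels, D)
        assert tree.bipartitions() == splits
        assert np.allclose(tree_path_lengths(tree, labels), D)

    def test_agreement_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        labels, D, _ = random_additive_tree(rng, 7)
        mine = nj_tree(labels, D)
        theirs = skbio_nj(DistanceMatrix(D, labels))
        their_splits = set()
        n = len(labels)
        ref = min(labels)
        all_set = frozenset(labels)
        for node in theirs.non_tips():
            clade = frozenset(t.name for t in node.tips())
            side = all_set - clade if ref in clade else clade
            if 2 <= len(side) <= n - 2:
                their_splits.add(side)
        assert mine.bipartitions() == their_splits

    def test_ultrametric_four_taxa_matches_single_linkage_grouping(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        # ultrametric: (A,B) at height 1, (C,D) at height 1, root at 3
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        labels = ["A", "B", "C", "D"]
        tree = nj_tree(labels, D)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        Z = linkage(squareform(D), method="single")
        flat = fcluster(Z, t=2, criterion="distance")
        groups = {
            frozenset(l for l, f in zip(labels, flat) if f == k)
            for k in set(flat)
        }
        assert groups == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_four_point_condition_recovery_small_sweep(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 7))
            labels, D, splits = random_additive_tree(rng, n)
            tree = nj_tree(labels, D)
            assert tree.bipartitions() == splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], np.zeros((2, 2)))


def _two_clade_msa(n_informative=40, n_noise=0, rng=None):
    # two clades of 3; informative columns all support the same split
    rows = {name: [] for name in ["a1", "a2", "a3", "b1", "b2", "b3"]}
    for _ in range(n_informative):
        for name in rows:
            rows[name].append("A" if name.startswith("a") else "R")
    if rng is not None:
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(n_noise):
            for name in rows:
                rows[name].append(letters[rng.integers(20)])
    return _msa([(name, "".join(chars)) for name, chars in rows.items()])


class TestBootstrapConsensus:
    def test_unanimous_split_gets_full_support(self):
        msa = _two_clade_msa()
        tree = bootstrap_consensus(msa, PhyloParams(seed=5, bootstrap_replicates=25))
        clades = {}
        def walk(node):
            for c in node.children:
                if not c.is_leaf():
                    clades[c.leaf_names()] = c.support
                walk(c)
        walk(tree.root)
        sides = {frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}
        assert any(s in clades and clades[s] == 100.0 for s in sides)

    def test_fixed_seed_is_deterministic(self, small_sim):
        msa = progressive_msa(small_sim.genome1[:8])
        masked = mask_columns(msa)
        params = PhyloParams(seed=9, bootstrap_replicates=20)
        t1 = bootstrap_consensus(masked, params)
        t2 = bootstrap_consensus(masked, params)
        assert t1.newick() == t2.newick()

    def test_two_planted_clades_retained(self):
        rng = np.random.default_rng(3)
        msa = _two_clade_msa(n_informative=40, n_noise=20, rng=rng)
        tree = bootstrap_consensus(msa, PhyloParams(seed=3))
        split = frozenset({"a1", "a2", "a3"})
        sides = tree.bipartitions()
        assert split in sides or frozenset({"b1", "b2", "b3"}) in sides

    def test_supports_invariant_to_row_permutation(self):
        rng = np.random.default_rng(12)
        msa = _two_clade_msa(n_informative=30, n_noise=10, rng=rng)
        permuted = _msa(list(reversed(msa.rows)))
        params = PhyloParams(seed=21, bootstrap_replicates=30)
        t1 = bootstrap_consensus(msa, params)
        t2 = bootstrap_consensus(permuted, params)
        assert t1.newick() == t2.newick()


def _star_tree(names):
    return Tree(root=TreeNode(children=[TreeNode(name=n) for n in names]))


class TestAssignSubfamilies:
    def test_star_tree_leaves_everything_unassigned(self):
        tree = _star_tree(["x", "y", "anchor1", "anchor2"])
        result = assign_subfamilies(tree, {"anchor1": "A", "anchor2": "B"})
        assert result.unassigned == ["x", "y"]

    def test_supported_clade_labels_its_members(self):
        clade = TreeNode(
            support=80.0,
            children=[TreeNode(name="anchor_della"), TreeNode(name="x"), TreeNode(name="y")],
        )
        other = TreeNode(
            support=90.0,
            children=[TreeNode(name="anchor_ham"), TreeNode(name="z")],
        )
        tree = Tree(root=TreeNode(children=[clade, other, TreeNode(name="w")]))
        result = assign_subfamilies(
            tree, {"anchor_della": "DELLA", "anchor_ham": "HAM"}
        )
        assert result.labels["x"] == result.labels["y"] == "DELLA"
        assert result.labels["z"] == "HAM"
        # w hangs off the root polytomy: on the unrooted tree it falls on the
        # HAM side of the DELLA-clade edge, whose only anchor label is HAM
        assert result.labels["w"] == "HAM"
        assert result.unassigned == []

    def test_mixed_anchor_sides_stay_unassigned(self):
        clades = [
            TreeNode(
                support=90.0,
                children=[TreeNode(name=f"anchor_{k}"), TreeNode(name=f"m{k}")],
            )
            for k in range(3)
        ]
        tree = Tree(root=TreeNode(children=clades + [TreeNode(name="w")]))
        result = assign_subfamilies(
            tree, {f"anchor_{k}": f"L{k}" for k in range(3)}
        )
        # every side containing w carries two anchor labels
        assert result.unassigned == ["w"]

    def test_missing_anchor_rejected(self):
        tree = _star_tree(["x", "y"])
        with pytest.raises(ValueError, match="missing"):
            assign_subfamilies(tree, {"ghost": "A"})

    def test_full_recovery_on_synthetic_family(self, small_sim):
        msa = progressive_msa(small_sim.genome1)
        masked = mask_columns(msa)
        labels, D = distance_matrix(masked)
        tree = nj_tree(labels, D)
        anchors = {}
        for record in small_sim.genome1:
            if record.subfamily not in anchors.values():
                anchors[record.id] = record.subfamily
        result = assign_subfamilies(tree, anchors)
        for record in small_sim.genome1:
            assert result.label(record.id) == record.subfamily
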