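"""p-distances, neighbor joining (vs. least-squares and skbio oracles),
bootstrap supports, midpoint rooting."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls
from skbio import DistanceMatrix, TreeNode

from cherry_rga.io.msa import Alignment
from cherry_rga.io.trees import parse_newick, write_newick
from cherry_rga.phylo import (
    PhyloConfig,
    bootstrap_support,
    leaf_bipartitions,
    midpoint_root,
    nj_tree,
    p_distance_matrix,
)
from cherry_rga.synthetic import evolve_alignment, random_binary_tree


def splits(tree):
    """Normalized non-trivial bipartitions of an (un)rooted tree."""
    names = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(names) - 1 or (1 < len(names - s) < len(names) - 1):
            out.add(min(s, names - s, key=lambda f: tuple(sorted(f))))
    return out


# ---------------------------------------------------------------------------
# least-squares topology oracle (brute force over all unrooted topologies)


def enumerate_topologies(names):
    base = TreeNode(
        children=[TreeNode(name=names[0]), TreeNode(name=names[1]), TreeNode(name=names[2])]
    )
    trees = [base]
    for nm in names[3:]:
        grown = []
        for t in trees:
            n_edges = sum(1 for _ in t.traverse(include_self=False))
            for k in range(n_edges):
                t2 = t.copy()
                target = [n for n in t2.traverse(include_self=False)][k]
                parent = target.parent
                parent.remove(target)
                mid = TreeNode()
                mid.append(target)
                mid.append(TreeNode(name=nm))
                parent.append(mid)
                grown.append(t2)
        trees = grown
    return trees


def least_squares_fit(topology, dm):
    """Non-negative least-squares branch lengths; returns (sse, lengths)."""
    ids = list(dm.ids)
    edges = [n for n in topology.traverse(include_self=False)]
    tipsets = [frozenset(t.name for t in e.tips()) or frozenset({e.name}) for e in edges]
    pairs = list(itertools.combinations(range(len(ids)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dm.data[i, j] for i, j in pairs])
    for row, (i, j) in enumerate(pairs):
        for col, ts in enumerate(tipsets):
            if (ids[i] in ts) != (ids[j] in ts):
                A[row, col] = 1.0
    x, _ = nnls(A, y)
    sse = float(((A @ x - y) ** 2).sum())
    return sse, dict(zip((id(e) for e in edges), x)), edges, x


WORKED = DistanceMatrix(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], ids=list("ABCD")
)


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        """Additive matrix -> ((A,B),(C,D)) with leaf branches 1,2,3,4 and
        internal branch 1; the LS oracle over all 3 topologies agrees."""
        tree = nj_tree(WORKED)
        assert splits(tree) == {frozenset({"A", "B"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = [n.length for n in tree.non_tips(include_self=False)]
        assert internal == pytest.approx([1.0])

        best_sse, best_top = min(
            (least_squares_fit(t, WORKED)[0], t) for t in enumerate_topologies(list("ABCD"))
        )
        assert best_sse == pytest.approx(0.0, abs=1e-18)
        assert splits(best_top) == splits(tree)

    def test_four_point_condition_of_worked_example(self):
        d = WORKED.data
        sums = sorted(
            [d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]]
        )
        assert sums[1] == sums[2] >= sums[0]

    def test_three_taxa_star(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3})

    @pytest.mark.parametrize("seed", range(12))
    def test_ls_oracle_agreement_on_random_additive_five_taxa(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"t{i}" for i in range(5)]
        true = random_binary_tree(names, rng, (0.5, 2.0))
        dm0 = true.tip_tip_distances()
        dm = DistanceMatrix(dm0.filter(sorted(dm0.ids)).data, ids=sorted(dm0.ids))
        mine = nj_tree(dm)
        scored = [(least_squares_fit(t, dm)[0], t) for t in enumerate_topologies(sorted(dm.ids))]
        best_sse = min(s for s, _ in scored)
        best_tops = [splits(t) for s, t in scored if s < best_sse + 1e-12]
        assert splits(mine) in best_tops

    def test_exact_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            names = [f"t{i}" for i in range(n)]
            true = random_binary_tree(names, rng, (0.3, 2.5))
            dm0 = true.tip_tip_distances()
            ids = sorted(dm0.ids)
            dm = DistanceMatrix(dm0.filter(ids).data, ids=ids)
            mine = nj_tree(dm)
            assert splits(mine) == splits(true)
            back = mine.tip_tip_distances().filter(ids)
            np.testing.assert_allclose(np.asarray(back.data), dm.data, atol=1e-9)

    def test_invariance_under_taxon_permutation(self):
        rng = np.random.default_rng(5)
        names = [f"t{i}" for i in range(7)]
        true = random_binary_tree(names, rng, (0.4, 1.5))
        dm0 = true.tip_tip_distances()
        ids = list(dm0.ids)
        dm = DistanceMatrix(dm0.filter(ids).data, ids=ids)
        t1 = nj_tree(dm)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        t2 = nj_tree(DistanceMatrix(dm.filter(perm).data, ids=perm))
        assert splits(t1) == splits(t2)
        d1 = t1.tip_tip_distances().filter(sorted(ids))
        d2 = t2.tip_tip_distances().filter(sorted(ids))
        np.testing.assert_allclose(np.asarray(d1.data), np.asarray(d2.data), atol=1e-9)

    def test_agrees_with_skbio_nj_on_generic_matrices(self):
        import skbio.tree

        rng = np.random.default_rng(9)
        for _ in range(5):
            tree = random_binary_tree([f"t{i}" for i in range(8)], rng, (0.05, 0.20))
            aln = evolve_alignment(tree, 400, rng)
            dm = p_distance_matrix(aln)
            assert splits(nj_tree(dm)) == splits(skbio.tree.nj(dm))

    def test_asymmetric_matrix_rejected(self):
        # skbio's DistanceMatrix enforces symmetry itself, so feed a bare
        # stand-in to exercise our own validation
        class Fake:
            data = np.array([[0.0, 1.0], [2.0, 0.0]])
            ids = ("a", "b")

        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(Fake())

    def test_negative_branch_clamped(self):
        # a non-additive matrix that drives one NJ branch negative
        dm = DistanceMatrix(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.01], [0.5, 0.5, 0.01, 0]],
            ids=list("abcd"),
        )
        tree = nj_tree(dm)
        assert all((n.length or 0.0) >= 0 for n in tree.traverse(include_self=False))


class TestPDistance:
    def test_single_mismatch(self):
        d = p_distance_matrix(Alignment(("a", "b"), ("ACGT", "ACGA")))
        assert d.data[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_ignores_gap_sites(self):
        d = p_distance_matrix(Alignment(("a", "b"), ("AC-T", "ACGT")))
        assert d.data[0, 1] == 0.0

    def test_x_treated_as_missing(self):
        d = p_distance_matrix(Alignment(("a", "b"), ("ACXT", "ACGA")))
        assert d.data[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion_drops_column_for_all(self):
        aln = Alignment(("a", "b", "c"), ("ACGT", "ACGT", "-CGA"))
        pair = p_distance_matrix(aln, "pairwise")
        comp = p_distance_matrix(aln, "complete")
        assert pair.data[0, 2] == pytest.approx(1 / 3)
        assert comp.data[0, 1] == 0.0
        assert comp.data[0, 2] == pytest.approx(1 / 3)
        assert comp.data[0, 1] == 0.0

    def test_identical_rows_zero_and_symmetry(self):
        rng = np.random.default_rng(3)
        tree = random_binary_tree([f"s{i}" for i in range(6)], rng)
        aln = evolve_alignment(tree, 120, rng)
        d = np.asarray(p_distance_matrix(aln).data)
        np.testing.assert_allclose(d, d.T)
        assert (np.diag(d) == 0).all()

    def test_no_comparable_sites_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            p_distance_matrix(Alignment(("a", "b"), ("A---", "-CCC")))


STRONG_SPLIT_ALN = Alignment(
    ("a1", "a2", "a3", "b1", "b2", "b3"),
    (
        "A" * 100 + "C" * 100,
        "A" * 100 + "C" * 99 + "D",
        "A" * 99 + "E" + "C" * 100,
        "W" * 100 + "Y" * 100,
        "W" * 100 + "Y" * 99 + "F",
        "W" * 99 + "H" + "Y" * 100,
    ),
)


class TestBootstrap:
    def test_overwhelming_split_gets_high_support(self):
        tree = bootstrap_support(STRONG_SPLIT_ALN, PhyloConfig(n_bootstrap=100, seed=1))
        supports = {
            frozenset(t.name for t in n.tips()): int(n.name)
            for n in tree.non_tips(include_self=False)
            if n.name
        }
        clan = [v for k, v in supports.items() if k in ({"a1", "a2", "a3"}, {"b1", "b2", "b3"})]
        assert clan and min(clan) >= 95

    def test_zero_replicates_returns_plain_tree(self):
        tree = bootstrap_support(STRONG_SPLIT_ALN, PhyloConfig(n_bootstrap=0, seed=1))
        assert all(n.name is None for n in tree.non_tips(include_self=False))

    def test_same_seed_same_supports(self):
        cfg = PhyloConfig(n_bootstrap=50, seed=77)
        t1 = bootstrap_support(STRONG_SPLIT_ALN, cfg)
        t2 = bootstrap_support(STRONG_SPLIT_ALN, cfg)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_lie_in_0_100(self):
        rng = np.random.default_rng(8)
        tree = random_binary_tree([f"s{i}" for i in range(7)], rng, (0.05, 0.3))
        aln = evolve_alignment(tree, 80, rng)
        boot = bootstrap_support(aln, PhyloConfig(n_bootstrap=60, seed=3))
        sup = [int(n.name) for n in boot.non_tips(include_self=False) if n.name]
        assert sup and all(0 <= s <= 100 for s in sup)


class TestMidpointRoot:
    def test_worked_example_root_on_d_branch(self):
        rooted = midpoint_root(nj_tree(WORKED))
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        # longest path B-D = 7 -> both ends 3.5 from the root
        assert depths["B"] == pytest.approx(3.5)
        assert depths["D"] == pytest.approx(3.5)
        # the root splits D's terminal branch
        d_tip = rooted.find("D")
        assert d_tip.parent is rooted

    def test_two_leaf_center(self):
        tree = parse_newick("(A:2,B:4);")
        rooted = midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths["A"] == pytest.approx(3.0)
        assert depths["B"] == pytest.approx(3.0)

    def test_rooting_preserves_pairwise_distances(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tree = random_binary_tree([f"t{i}" for i in range(6)], rng, (0.1, 1.0))
            dm = tree.tip_tip_distances()
            ids = sorted(dm.ids)
            rooted = midpoint_root(tree)
            back = rooted.tip_tip_distances().filter(ids)
            np.testing.assert_allclose(
                np.asarray(back.data), np.asarray(dm.filter(ids).data), atol=1e-9
            )

    def test_supports_stay_with_their_bipartition(self):
        tree = parse_newick("((A:1,B:2)100:1,(C:3,(E:1,F:1)88:2)75:1,D:4);")
        rooted = midpoint_root(tree)
        sup = {
            frozenset(t.name for t in n.tips()): n.name
            for n in rooted.non_tips(include_self=False)
            if n.name
        }
        assert sup.get(frozenset({"E", "F"})) == "88"
        assert sup.get(frozenset({"A", "B"})) == "100"
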