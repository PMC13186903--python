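"""Classical MDS, UPGMA and breed-dominance assignment."""

import itertools

import numpy as np
import pytest

from haplostrat.asd import DistanceMatrix
from haplostrat.io import EXPERIMENTAL, REF_A, REF_B, PanelLabels
from haplostrat.structure import (
    A_DOMINANT,
    B_DOMINANT,
    UNASSIGNED,
    assign_breed,
    classical_mds,
    leaf_order,
    to_newick,
    upgma,
)


def euclidean_dm(points, ids=None):
    x = np.asarray(points, dtype=float)
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    ids = ids or [f"p{i}" for i in range(len(x))]
    return DistanceMatrix(ids, d)


def brute_force_upgma(ids, d):
    """Reference UPGMA that recomputes every cluster-pair average from the
    original matrix at each step (no Lance-Williams update)."""
    d = np.asarray(d, dtype=float)
    pos = {a: i for i, a in enumerate(ids)}
    clusters = {a: frozenset([a]) for a in ids}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            avg = np.mean(
                [d[pos[x], pos[y]] for x in clusters[a] for y in clusters[b]]
            )
            key = (avg, a, b)
            if best is None or key < best:
                best = key
        avg, a, b = best
        merges.append((frozenset(clusters[a] | clusters[b]), avg / 2))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges


def tree_merges(tree):
    out = []

    def visit(node):
        if node.is_leaf:
            return
        out.append((frozenset(node.leaves()), node.height))
        for c in node.children:
            visit(c)

    visit(tree.root)
    return sorted(out, key=lambda m: (m[1], sorted(m[0])))


class TestClassicalMds:
    def test_reproduces_planar_345_triangle(self):
        dm = euclidean_dm([(0, 0), (3, 0), (0, 4)])
        emb = classical_mds(dm, dims=2)
        d_emb = np.sqrt(
            ((emb.coordinates[:, None] - emb.coordinates[None]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(d_emb, dm.values, atol=1e-8)
        assert emb.stress < 1e-12

    def test_identical_points_coincide(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]),
        )
        emb = classical_mds(dm, dims=2)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-6)

    def test_eigenvalues_non_increasing_and_sign_convention(self, small_cohort):
        from haplostrat.asd import asd_matrix
        from haplostrat.blocks import partition_blocks
        from haplostrat.io import filter_informative

        gm, smap, _ = filter_informative(small_cohort.genotypes, small_cohort.snp_map)
        dm = asd_matrix(gm, partition_blocks(smap))
        emb = classical_mds(dm, dims=2, panels=small_cohort.labels)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)
        ia = [dm.ids.index(a) for a in small_cohort.labels.ref_a_ids]
        assert emb.coordinates[ia, 0].mean() >= 0
        assert emb.coordinates[ia, 1].mean() >= 0

    def test_dims_exceeding_n_rejected(self):
        dm = euclidean_dm([(0, 0), (1, 0)])
        with pytest.raises(ValueError, match="dims"):
            classical_mds(dm, dims=3)

    def test_non_euclidean_axes_zero_filled(self):
        # a metric violating the Euclidean condition in 3 dims: star-like
        d = np.array(
            [
                [0, 1, 1, 1],
                [1, 0, 2, 2],
                [1, 2, 0, 2],
                [1, 2, 2, 0],
            ],
            dtype=float,
        ) / 2.0
        dm = DistanceMatrix(list("abcd"), d)
        emb = classical_mds(dm, dims=4)
        assert emb.n_negative_axes >= 1
        assert np.all(emb.coordinates[:, -emb.n_negative_axes:] == 0)


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.root.leaves()) == ["a", "b"]

    def test_three_taxa_hand_example(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float) / 10
        dm = DistanceMatrix(["A", "B", "C"], d)
        tree = upgma(dm)
        merges = tree_merges(tree)
        assert merges[0] == (frozenset({"A", "B"}), pytest.approx(0.1))
        assert merges[1][0] == frozenset({"A", "B", "C"})
        assert merges[1][1] == pytest.approx(0.3)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            ids = [f"t{i}" for i in range(6)]
            x = rng.random((6, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            dm = DistanceMatrix(ids, d / d.max())
            tree = upgma(dm)
            expected = sorted(
                brute_force_upgma(ids, dm.values), key=lambda m: (m[1], sorted(m[0]))
            )
            got = tree_merges(tree)
            assert [m[0] for m in got] == [m[0] for m in expected]
            np.testing.assert_allclose(
                [m[1] for m in got], [m[1] for m in expected], atol=1e-12
            )

    def test_heights_monotone_to_root(self, rng):
        x = rng.random((10, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"t{i}" for i in range(10)], d / d.max())
        tree = upgma(dm)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree.root)

    def test_ultrametric_input_reproduces_cophenetic_matrix(self):
        # build an ultrametric by hand: ((a,b):1,(c,d):2):3 with exact
        # binary-representable heights
        coph = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0],
            ],
            dtype=float,
        ) / 8.0
        dm = DistanceMatrix(list("abcd"), coph)
        tree = upgma(dm)
        np.testing.assert_array_equal(tree.cophenetic(), coph)

    def test_newick_and_leaf_order_deterministic(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float) / 10
        dm1 = DistanceMatrix(["B", "A", "C"], d[np.ix_([1, 0, 2], [1, 0, 2])])
        dm2 = DistanceMatrix(["A", "B", "C"], d)
        assert leaf_order(upgma(dm1)) == leaf_order(upgma(dm2)) == ["A", "B", "C"]
        assert to_newick(upgma(dm1)) == to_newick(upgma(dm2))

    def test_two_leaf_order_sorted(self):
        dm = DistanceMatrix(["b", "a"], np.array([[0, 0.4], [0.4, 0]]))
        assert leaf_order(upgma(dm)) == ["a", "b"]


class TestAssignBreed:
    def _labels(self, ref_a, ref_b, experimental):
        roles = {a: REF_A for a in ref_a}
        roles.update({b: REF_B for b in ref_b})
        roles.update({e: EXPERIMENTAL for e in experimental})
        return PanelLabels(roles)

    def test_equidistant_animal_unassigned(self):
        d = np.array(
            [[0, 0.4, 0.2], [0.4, 0, 0.2], [0.2, 0.2, 0]], dtype=float
        )
        dm = DistanceMatrix(["ra", "rb", "x"], d)
        ba = assign_breed(dm, self._labels(["ra"], ["rb"], ["x"]))
        assert ba.label_of("x") == UNASSIGNED
        assert ba.frame["score"].iloc[0] == 0.0

    def test_score_formula(self):
        d = np.zeros((3, 3))
        d[2, 0] = d[0, 2] = 0.2  # to panel A
        d[2, 1] = d[1, 2] = 0.3  # to panel B
        d[0, 1] = d[1, 0] = 0.5
        dm = DistanceMatrix(["ra", "rb", "x"], d)
        ba = assign_breed(dm, self._labels(["ra"], ["rb"], ["x"]))
        assert ba.frame["score"].iloc[0] == pytest.approx(0.2)
        assert ba.label_of("x") == A_DOMINANT

    def test_antisymmetric_under_panel_swap(self):
        d = np.zeros((4, 4))
        d[2, 0] = d[0, 2] = 0.15
        d[2, 1] = d[1, 2] = 0.35
        d[3, 0] = d[0, 3] = 0.30
        d[3, 1] = d[1, 3] = 0.10
        d[0, 1] = d[1, 0] = 0.5
        d[2, 3] = d[3, 2] = 0.2
        dm = DistanceMatrix(["ra", "rb", "x", "y"], d)
        ba1 = assign_breed(dm, self._labels(["ra"], ["rb"], ["x", "y"]))
        ba2 = assign_breed(dm, self._labels(["rb"], ["ra"], ["x", "y"]))
        np.testing.assert_allclose(
            ba1.frame["score"].to_numpy(), -ba2.frame["score"].to_numpy()
        )
        assert ba1.label_of("x") == A_DOMINANT and ba2.label_of("x") == B_DOMINANT

    def test_duplicated_reference_changes_nothing(self):
        d = np.zeros((4, 4))
        # rb duplicated as rb2 (distance pattern identical)
        d[3, 0] = d[0, 3] = 0.2
        d[3, 1] = d[1, 3] = 0.3
        d[3, 2] = d[2, 3] = 0.3
        d[0, 1] = d[1, 0] = 0.5
        d[0, 2] = d[2, 0] = 0.5
        dm = DistanceMatrix(["ra", "rb", "rb2", "x"], d)
        ba_dup = assign_breed(dm, self._labels(["ra"], ["rb", "rb2"], ["x"]))
        dm_single = dm.submatrix(["ra", "rb", "x"])
        ba = assign_breed(dm_single, self._labels(["ra"], ["rb"], ["x"]))
        assert ba_dup.frame["score"].iloc[0] == pytest.approx(
            ba.frame["score"].iloc[0]
        )

    def test_tie_band_widens_unassigned(self):
        d = np.zeros((3, 3))
        d[2, 0] = d[0, 2] = 0.28
        d[2, 1] = d[1, 2] = 0.32
        d[0, 1] = d[1, 0] = 0.5
        dm = DistanceMatrix(["ra", "rb", "x"], d)
        labels = self._labels(["ra"], ["rb"], ["x"])
        assert assign_breed(dm, labels, tie_band=0.0).label_of("x") == A_DOMINANT
        assert assign_breed(dm, labels, tie_band=0.1).label_of("x") == UNASSIGNED

    def test_empty_panel_rejected(self):
        dm = DistanceMatrix(["ra", "x"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError, match="non-empty"):
            assign_breed(dm, self._labels(["ra"], [], ["x"]))

    def test_missing_experimental_animal_rejected(self):
        dm = DistanceMatrix(["ra", "rb"], np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValueError, match="absent"):
            assign_breed(dm, self._labels(["ra"], ["rb"], ["ghost"]))

    def test_recovers_majority_ancestry(self, small_cohort):
        from haplostrat.asd import asd_matrix
        from haplostrat.blocks import partition_blocks
        from haplostrat.io import filter_informative

        gm, smap, _ = filter_informative(small_cohort.genotypes, small_cohort.snp_map)
        dm = asd_matrix(gm, partition_blocks(smap))
        ba = assign_breed(dm, small_cohort.labels)
        correct = [
            (ba.label_of(a) == A_DOMINANT) == (small_cohort.true_alpha[a] >= 0.5)
            for a in small_cohort.labels.experimental_ids
        ]
        assert np.mean(correct) >= 0.95
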