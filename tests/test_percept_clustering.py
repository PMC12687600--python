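"""Location dissimilarity, complete linkage, cutoff sweeps."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from smbench.percept_clustering import (
    DEFAULT_CUTOFF_GRID,
    ClusterCurve,
    DissimilarityMatrix,
    build_dissimilarity_matrix,
    cluster_count,
    cluster_curve,
    cluster_labels,
    complete_linkage,
    location_dissimilarity,
    nonpainful_predicate,
    summarize_sessions,
)
from smbench.percept_maps import PerceptDrawing


def random_masks(rng, n, shape=(12, 12), p=0.35):
    masks = []
    while len(masks) < n:
        m = rng.random(shape) < p
        if m.any():
            masks.append(m)
    return masks


def drawings_from_masks(masks, categories=frozenset({"tactile"})):
    return [
        PerceptDrawing(
            contact_id=f"C{i}", nerve="median", mask=m, categories=categories
        )
        for i, m in enumerate(masks)
    ]


def random_dissimilarity(rng, n):
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(labels=tuple(f"L{i}" for i in range(n)), D=D)


class TestLocationDissimilarity:
    def test_identical_masks_score_zero(self):
        m = np.eye(4, dtype=bool)
        assert location_dissimilarity(m, m) == 0.0

    def test_disjoint_masks_score_one(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0], b[2] = True, True
        assert location_dissimilarity(a, b) == 1.0

    def test_nested_blocks(self):
        # 4-px block inside an 8-px block: 1 - 4/8 = 0.5
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0:2, 0:2] = True
        b[0:2, 0:4] = True
        assert location_dissimilarity(a, b) == pytest.approx(0.5)

    def test_both_empty_masks_rejected(self):
        z = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            location_dissimilarity(z, z)

    def test_triangle_inequality_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c = random_masks(rng, 3, shape=(8, 8))
            dab = location_dissimilarity(a, b)
            dbc = location_dissimilarity(b, c)
            dac = location_dissimilarity(a, c)
            assert dac <= dab + dbc + 1e-12


class TestBuildDissimilarityMatrix:
    def test_painful_percepts_excluded_by_default(self):
        rng = np.random.default_rng(0)
        masks = random_masks(rng, 3)
        ds = drawings_from_masks(masks)
        ds[1] = PerceptDrawing(
            contact_id="C1",
            nerve="median",
            mask=masks[1],
            categories=frozenset({"tactile", "painful"}),
        )
        Dm = build_dissimilarity_matrix(ds)
        assert Dm.n == 2
        assert Dm.labels == ("C0", "C2")

    def test_identical_survivors_give_zero_matrix(self):
        m = np.eye(5, dtype=bool)
        Dm = build_dissimilarity_matrix(drawings_from_masks([m, m, m]))
        np.testing.assert_allclose(Dm.D, 0.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        masks = random_masks(rng, 5)
        Dm = build_dissimilarity_matrix(drawings_from_masks(masks))
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else location_dissimilarity(masks[i], masks[j])
                assert Dm.D[i, j] == pytest.approx(expect)

    def test_too_few_survivors_names_the_filter(self):
        ds = drawings_from_masks(
            [np.ones((2, 2), dtype=bool)], categories=frozenset({"painful"})
        )
        with pytest.raises(ValueError, match="nonpainful_predicate"):
            build_dissimilarity_matrix(ds)


class TestCompleteLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        Dm = DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = complete_linkage(Dm)
        assert tree.merges == ((0, 1, 0.4, 2),)

    def test_three_leaf_hand_run(self):
        # D(a,b)=0.3, D(a,c)=D(b,c)=0.9: merge {a,b} at 0.3, then at 0.9
        D = np.array([[0.0, 0.3, 0.9], [0.3, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = complete_linkage(DissimilarityMatrix(("a", "b", "c"), D))
        np.testing.assert_allclose(tree.heights, [0.3, 0.9])
        assert cluster_count(tree, 0.7) == 2
        assert cluster_count(tree, 0.9) == 1  # inclusive cutoff keeps 0.9 merge

    def test_heights_match_scipy_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(2, 8)
            Dm = random_dissimilarity(rng, n)
            tree = complete_linkage(Dm)
            Z = linkage(squareform(Dm.D, checks=False), method="complete")
            np.testing.assert_allclose(tree.heights, Z[:, 2], atol=1e-12)

    def test_counts_match_scipy_fcluster(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            Dm = random_dissimilarity(rng, n)
            tree = complete_linkage(Dm)
            Z = linkage(squareform(Dm.D, checks=False), method="complete")
            for cutoff in (0.2, 0.5, 0.8, 1.0):
                expect = len(set(fcluster(Z, t=cutoff, criterion="distance")))
                assert cluster_count(tree, cutoff) == expect

    def test_rejects_asymmetric_or_nan_matrix(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.2], [0.3, 0.0]]))
        with pytest.raises(ValueError):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestClusterCount:
    def test_all_distinct_at_low_cutoff(self):
        n = 5
        D = 1.0 - np.eye(n)
        tree = complete_linkage(
            DissimilarityMatrix(tuple("abcde"), D)
        )
        assert cluster_count(tree, 0.7) == n
        assert cluster_count(tree, 1.0) == 1  # inclusive at height 1

    def test_all_identical_at_any_cutoff(self):
        D = np.zeros((4, 4))
        tree = complete_linkage(DissimilarityMatrix(tuple("abcd"), D))
        assert cluster_count(tree, 0.01) == 1

    def test_within_cluster_dissimilarity_bounded_by_cutoff(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            Dm = random_dissimilarity(rng, n)
            tree = complete_linkage(Dm)
            for cutoff in (0.3, 0.6, 0.9):
                labels = cluster_labels(tree, cutoff)
                for k in range(labels.max() + 1):
                    idx = np.flatnonzero(labels == k)
                    if len(idx) > 1:
                        assert Dm.D[np.ix_(idx, idx)].max() <= cutoff + 1e-12


class TestClusterCurve:
    def test_single_percept_curve_is_constant_one(self):
        m = np.ones((3, 3), dtype=bool)
        curve = cluster_curve(drawings_from_masks([m]))
        assert np.all(curve.counts == 1)

    def test_grid_endpoints_consistent_with_direct_counts(self):
        rng = np.random.default_rng(5)
        ds = drawings_from_masks(random_masks(rng, 6))
        curve = cluster_curve(ds)
        tree = complete_linkage(build_dissimilarity_matrix(ds))
        assert curve.count_at(0.01) == cluster_count(tree, 0.01)
        assert curve.count_at(1.0) == cluster_count(tree, 1.0)

    def test_counts_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(6)
        ds = drawings_from_masks(random_masks(rng, 8))
        curve = cluster_curve(ds)
        assert np.all(np.diff(curve.counts) <= 0)

    def test_permuting_drawing_order_preserves_counts(self):
        rng = np.random.default_rng(7)
        ds = drawings_from_masks(random_masks(rng, 7))
        base = cluster_curve(ds).counts
        for _ in range(5):
            perm = rng.permutation(len(ds))
            np.testing.assert_array_equal(
                cluster_curve([ds[i] for i in perm]).counts, base
            )


class TestSummarizeSessions:
    def test_mean_and_se_arithmetic(self):
        curves = [
            ClusterCurve(
                cutoffs=np.array([0.7]), counts=np.array([c]), system_id="sys"
            )
            for c in (7, 6, 9)
        ]
        out = summarize_sessions(curves, cutoffs=(0.7,))
        mean, se = out["sys"][0.7]
        assert mean == pytest.approx(7.333, abs=1e-3)
        assert se == pytest.approx(0.882, abs=1e-3)

    def test_single_or_identical_sessions_have_zero_se(self):
        one = [ClusterCurve(np.array([0.7]), np.array([5]), system_id="a")]
        same = [
            ClusterCurve(np.array([0.7]), np.array([4]), system_id="b")
            for _ in range(3)
        ]
        out = summarize_sessions(one + same, cutoffs=(0.7,))
        assert out["a"][0.7] == (5.0, 0.0)
        assert out["b"][0.7] == (4.0, 0.0)
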