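import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics import silhouette_score as sk_silhouette

from comedclust.distance import DistanceMatrix, distance_matrix
from comedclust.errors import ConfigError, DataError
from comedclust.exposure import ExposureProfile, N_WINDOWS
from comedclust.hca import (
    ClusterAssignment,
    average_linkage,
    centroid_linkage,
    cut_tree,
    leaf_order,
    read_assignment,
    read_linkage,
    silhouette_score,
    write_assignment,
    write_linkage,
)

from conftest import random_distance_matrix
from oracles import naive_centroid_linkage, naive_silhouette


class TestCentroidLinkage:
    def test_two_leaves(self):
        t = centroid_linkage(np.array([[0.0, 2.5], [2.5, 0.0]]))
        np.testing.assert_allclose(t.merges, [[0, 1, 2.5, 2]])

    def test_three_leaf_hand_case(self):
        # AB=1, AC=BC=5: merge (0,1) at 1, then C joins at sqrt(24.75)
        # by the centroid recurrence (25+25)/2 - 1/4.
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0.0]])
        t = centroid_linkage(d)
        np.testing.assert_allclose(
            t.merges, [[0, 1, 1.0, 2], [2, 3, np.sqrt(24.75), 3]]
        )

    def test_all_identical_merge_at_zero_with_lexicographic_ties(self):
        t = centroid_linkage(np.zeros((4, 4)))
        assert np.all(t.merges[:, 2] == 0.0)
        # ties broken by smallest cluster-id pair
        np.testing.assert_array_equal(
            t.merges[:, :2], [[0, 1], [2, 3], [4, 5]]
        )

    def test_matches_naive_recomputation(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 25))
            sq = random_distance_matrix(rng, n)
            ours = centroid_linkage(sq).merges
            ref = naive_centroid_linkage(sq)
            np.testing.assert_array_equal(ours[:, :2], ref[:, :2])
            np.testing.assert_allclose(ours[:, 2], ref[:, 2], rtol=1e-9, atol=1e-12)
            np.testing.assert_array_equal(ours[:, 3], ref[:, 3])

    def test_matches_scipy_centroid(self, rng):
        # scipy applies the same centroid recurrence to a condensed matrix
        for _ in range(10):
            n = int(rng.integers(3, 40))
            sq = random_distance_matrix(rng, n)
            ours = centroid_linkage(sq).merges
            Z = sch.linkage(squareform(sq, checks=False), method="centroid")
            np.testing.assert_array_equal(
                np.sort(ours[:, :2], axis=1), np.sort(Z[:, :2], axis=1)
            )
            np.testing.assert_allclose(ours[:, 2], Z[:, 2], rtol=1e-8, atol=1e-10)

    def test_rejects_tiny_or_asymmetric(self):
        with pytest.raises(DataError):
            centroid_linkage(np.zeros((1, 1)))
        with pytest.raises(DataError, match="symmetric"):
            centroid_linkage(np.array([[0, 1.0], [2.0, 0]]))

    def test_relabeling_equivariance(self, rng):
        n = 9
        sq = random_distance_matrix(rng, n)
        perm = rng.permutation(n)
        labels = cut_tree(centroid_linkage(sq), k=3).labels
        labels_perm = cut_tree(centroid_linkage(sq[np.ix_(perm, perm)]), k=3).labels
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_ids_travel_from_distance_matrix(self):
        dm = DistanceMatrix.from_square(["a", "b", "c"], random_distance_matrix(np.random.default_rng(0), 3))
        tree = centroid_linkage(dm)
        assert tree.ids == ("a", "b", "c")
        assert cut_tree(tree, k=2).ids == ("a", "b", "c")

    def test_average_linkage_option_matches_scipy(self, rng):
        sq = random_distance_matrix(rng, 12)
        Z = sch.linkage(squareform(sq, checks=False), method="average")
        np.testing.assert_allclose(average_linkage(sq).merges, Z)


class TestCutTree:
    @pytest.fixture()
    def tree(self, rng):
        return centroid_linkage(random_distance_matrix(rng, 10))

    def test_extreme_cuts(self, tree):
        assert cut_tree(tree, k=10).k == 10
        assert cut_tree(tree, k=1).k == 1

    def test_k_out_of_range(self, tree):
        for bad in (0, 11):
            with pytest.raises(ConfigError):
                cut_tree(tree, k=bad)
        with pytest.raises(ConfigError):
            cut_tree(tree, k=2, height=1.0)
        with pytest.raises(ConfigError):
            cut_tree(tree)

    def test_height_cut_spans_merges(self, tree):
        heights = tree.merges[:, 2]
        everyone = cut_tree(tree, height=float(heights.max()))
        assert everyone.k == 1
        nobody = cut_tree(tree, height=0.0)
        assert nobody.k == 10

    def test_labels_by_first_appearance(self, tree):
        labels = cut_tree(tree, k=4).labels
        seen = []
        for v in labels:
            if v not in seen:
                seen.append(v)
        assert seen == sorted(seen)  # 1, 2, 3, 4 in first-appearance order

    def test_planted_two_blob_recovery(self):
        # two anatomically disjoint chronic exposure groups
        profiles = [
            ExposureProfile(
                f"P{i}",
                tuple(
                    frozenset({"N02BE01", "R03AC02"} if i < 10 else {"N02BE01", "N06AB04"})
                    for _ in range(N_WINDOWS)
                ),
            )
            for i in range(20)
        ]
        dm = distance_matrix(profiles)
        got = cut_tree(centroid_linkage(dm), k=2).labels
        planted = [1] * 10 + [2] * 10
        assert adjusted_rand_score(planted, got) == 1.0


class TestSilhouette:
    def test_perfect_separation(self):
        sq = np.zeros((4, 4))
        sq[:2, 2:] = 5.0
        sq[2:, :2] = 5.0
        assert silhouette_score(sq, [1, 1, 2, 2]) == 1.0

    def test_all_singletons_convention(self, rng):
        sq = random_distance_matrix(rng, 5)
        assert silhouette_score(sq, [1, 2, 3, 4, 5]) == 0.0

    def test_matches_brute_force_and_sklearn(self, rng):
        for n, k in [(4, 2), (7, 3), (10, 4)]:
            sq = random_distance_matrix(rng, n)
            labels = 1 + rng.integers(0, k, size=n)
            labels[:k] = np.arange(1, k + 1)  # ensure every cluster occupied
            ours = silhouette_score(sq, labels)
            assert ours == pytest.approx(naive_silhouette(sq, labels), abs=1e-12)
            if np.all(np.bincount(labels)[1:] > 0) and len(set(labels)) < n:
                assert ours == pytest.approx(
                    sk_silhouette(sq, labels, metric="precomputed"), abs=1e-12
                )

    def test_requires_two_clusters(self, rng):
        with pytest.raises(DataError):
            silhouette_score(random_distance_matrix(rng, 4), [1, 1, 1, 1])


class TestLeafOrder:
    def test_two_leaves(self):
        t = centroid_linkage(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(leaf_order(t), [0, 1])

    def test_tie_break_determinism_on_star(self):
        t = centroid_linkage(np.ones((4, 4)) - np.eye(4))
        np.testing.assert_array_equal(leaf_order(t), [0, 1, 2, 3])

    def test_first_merge_adjacent_and_permutation(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            t = centroid_linkage(random_distance_matrix(rng, n))
            order = leaf_order(t)
            assert sorted(order) == list(range(n))
            a, b = int(t.merges[0, 0]), int(t.merges[0, 1])
            pos = {int(v): i for i, v in enumerate(order)}
            assert abs(pos[a] - pos[b]) == 1


class TestIO:
    def test_linkage_roundtrip(self, tmp_path, rng):
        tree = centroid_linkage(random_distance_matrix(rng, 8))
        path = tmp_path / "linkage.csv"
        write_linkage(tree, path)
        back = read_linkage(path)
        assert back.n_leaves == 8
        np.testing.assert_array_equal(back.merges, tree.merges)

    def test_assignment_roundtrip(self, tmp_path):
        a = ClusterAssignment(("x", "y", "z"), np.array([1, 2, 1]), 2)
        path = tmp_path / "assignment.csv"
        write_assignment(a, path)
        back = read_assignment(path)
        assert back.ids == a.ids and back.k == 2
        np.testing.assert_array_equal(back.labels, a.labels)

    def test_assignment_validation(self):
        with pytest.raises(DataError, match="no empty cluster"):
            ClusterAssignment(("x", "y"), np.array([1, 3]), 3)
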