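import numpy as np
import pytest

from oracles import brute_dbi, brute_distance, brute_silhouette
from tadcluster.cluster import (
    ClusterAssignment,
    cluster_features,
    cluster_quality_report,
    davies_bouldin,
    distance,
    elbow_k,
    em_cluster,
    estimate_k_han,
    hierarchical_cluster,
    k_search_window,
    kmeans_cluster,
    silhouette,
)
from tadcluster.features import FeatureTable

from conftest import random_instance


def _table(x):
    x = np.asarray(x, float)
    return FeatureTable(vectors=x, bin_index=np.arange(len(x)), n_bins=len(x))


def _partition(labels):
    return {frozenset(np.flatnonzero(labels == c).tolist()) for c in set(labels)}


TOY = _table([[0.0, 0.0], [0.1, 0.1], [10.0, 10.0], [10.1, 10.1]])
TOY_PARTITION = {frozenset({0, 1}), frozenset({2, 3})}


class TestDistance:
    @pytest.mark.parametrize(
        "u, v, metric, expected",
        [
            ((0, 0), (3, 4), "euclidean", 5.0),
            ((0, 0), (3, 4), "cityblock", 7.0),
            ((1, 2, 3), (2, 4, 6), "pearson", 0.0),
            ((1, 2, 3), (3, 2, 1), "pearson", 2.0),  # perfectly anti-correlated
        ],
    )
    def test_known_values(self, u, v, metric, expected):
        assert distance(u, v, metric) == pytest.approx(expected)

    def test_constant_vector_under_pearson_rejected(self):
        with pytest.raises(ValueError):
            distance((1, 1, 1), (1, 2, 3), "pearson")

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.normal(size=(2, 6))
            for metric in ("euclidean", "cityblock", "pearson"):
                assert distance(u, v, metric) == pytest.approx(
                    brute_distance(u, v, metric), abs=1e-12
                )


class TestKmeans:
    @pytest.mark.parametrize("metric", ["euclidean", "cityblock"])
    def test_separated_toy(self, metric):
        a = kmeans_cluster(TOY, 2, metric=metric, seed=0)
        assert _partition(a.labels) == TOY_PARTITION

    def test_k_equals_n_gives_singletons(self):
        a = kmeans_cluster(TOY, 4, seed=0)
        assert len(set(a.labels.tolist())) == 4
        assert a.within_cluster_variance == pytest.approx(0.0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(TOY, 5, seed=0)

    def test_deterministic_given_seed(self, benchmark_features):
        a = kmeans_cluster(benchmark_features, 5, seed=42)
        b = kmeans_cluster(benchmark_features, 5, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("metric", ["euclidean", "pearson", "cityblock"])
    def test_planted_blocks_recovered(self, benchmark_features, metric):
        # the five planted blocks have distinct means, so the optimal
        # 5-partition is the blocks themselves
        truth = [0] * 8 + [1] * 6 + [2] * 6 + [3] * 5 + [4] * 5
        a = kmeans_cluster(benchmark_features, 5, metric=metric, seed=1)
        assert _partition(a.labels) == _partition(np.array(truth))


class TestHierarchical:
    def test_separated_toy(self):
        a = hierarchical_cluster(TOY, 2)
        assert _partition(a.labels) == TOY_PARTITION

    def test_k1_single_cluster(self):
        a = hierarchical_cluster(TOY, 1)
        assert set(a.labels.tolist()) == {0}

    @pytest.mark.parametrize("metric", ["euclidean", "pearson", "cityblock"])
    def test_planted_blocks_recovered(self, benchmark_features, metric):
        truth = [0] * 8 + [1] * 6 + [2] * 6 + [3] * 5 + [4] * 5
        a = hierarchical_cluster(benchmark_features, 5, metric=metric)
        assert _partition(a.labels) == _partition(np.array(truth))

    def test_ward_requires_euclidean(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(TOY, 2, metric="cityblock", linkage="ward")


class TestEM:
    def test_separated_toy(self):
        a = em_cluster(TOY, 2, seed=0)
        assert _partition(a.labels) == TOY_PARTITION

    def test_planted_blocks_recovered(self, benchmark_features):
        truth = [0] * 8 + [1] * 6 + [2] * 6 + [3] * 5 + [4] * 5
        a = em_cluster(benchmark_features, 5, seed=1)
        assert _partition(a.labels) == _partition(np.array(truth))

    def test_duplicate_rows_survive_variance_floor(self):
        f = _table([[1.0, 2.0]] * 6)
        a = em_cluster(f, 2, seed=0)
        assert len(a.labels) == 6  # converges without error despite zero spread


class TestKSelection:
    @pytest.mark.parametrize("n, expected", [(30, 4), (2, 2), (200, 10), (50, 5)])
    def test_sqrt_rule(self, n, expected):
        assert estimate_k_han(n) == expected

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_k_han(1)

    @pytest.mark.parametrize(
        "k_est, n, expected",
        [(4, 30, (2, 14)), (15, 1000, (5, 25)), (2, 4, (2, 3))],
    )
    def test_search_window(self, k_est, n, expected):
        assert k_search_window(k_est, n) == expected

    def test_elbow_on_planted_blocks(self, benchmark_features):
        k, curve = elbow_k(benchmark_features, 2, 10, seed=3)
        assert k == 5
        assert len(curve) == 9
        assert all(0 <= c <= 100 for c in curve)

    def test_elbow_two_blobs(self):
        rng = np.random.default_rng(12)
        x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        k, _ = elbow_k(_table(x), 2, 6, seed=0)
        assert k == 2

    def test_elbow_clips_k_max(self):
        with pytest.warns(UserWarning):
            k, curve = elbow_k(TOY, 2, 10, seed=0)
        assert len(curve) == 2  # k = 2, 3 only for 4 rows


class TestQualityIndices:
    def test_dbi_singletons_zero(self):
        f = _table([[0.0], [10.0]])
        a = ClusterAssignment(labels=[0, 1], k=2, algorithm="KM")
        assert davies_bouldin(f, a) == pytest.approx(0.0)

    def test_dbi_hand_example(self):
        # clusters {0,2} and {10,12}: spreads 1 and 1, centroid gap 10
        f = _table([[0.0], [2.0], [10.0], [12.0]])
        a = ClusterAssignment(labels=[0, 0, 1, 1], k=2, algorithm="KM")
        assert davies_bouldin(f, a) == pytest.approx(0.2)

    def test_dbi_coincident_centroids_rejected(self):
        f = _table([[0.0], [2.0], [0.0], [2.0]])
        a = ClusterAssignment(labels=[0, 0, 1, 1], k=2, algorithm="KM")
        with pytest.raises(ValueError):
            davies_bouldin(f, a)

    def test_silhouette_hand_example(self):
        f = _table([[0.0], [1.0], [10.0], [11.0]])
        a = ClusterAssignment(labels=[0, 0, 1, 1], k=2, algorithm="KM")
        si, per_point = silhouette(f, a)
        assert per_point[0] == pytest.approx(9.5 / 10.5)
        assert si == pytest.approx(brute_silhouette(f.vectors, a.labels))

    def test_silhouette_perfect_separation(self):
        f = _table([[0.0], [0.0], [9.0], [9.0]])
        a = ClusterAssignment(labels=[0, 0, 1, 1], k=2, algorithm="KM")
        si, _ = silhouette(f, a)
        assert si == pytest.approx(1.0)

    def test_silhouette_all_singletons_zero(self):
        f = _table([[0.0], [4.0], [9.0]])
        a = ClusterAssignment(labels=[0, 1, 2], k=3, algorithm="KM")
        si, _ = silhouette(f, a)
        assert si == pytest.approx(0.0)

    def test_one_cluster_rejected(self):
        f = _table([[0.0], [1.0]])
        a = ClusterAssignment(labels=[0, 0], k=1, algorithm="HC")
        with pytest.raises(ValueError):
            silhouette(f, a)

    @pytest.mark.parametrize("metric", ["euclidean", "cityblock"])
    def test_matches_brute_force_on_random_instances(self, metric):
        rng = np.random.default_rng(99)
        for _ in range(50):
            f, labels, k = random_instance(rng)
            a = ClusterAssignment(labels=labels, k=k, algorithm="KM")
            rep = cluster_quality_report(f, a, metric)
            assert rep.dbi == pytest.approx(brute_dbi(f.vectors, labels, metric), abs=1e-9)
            assert rep.si == pytest.approx(
                brute_silhouette(f.vectors, labels, metric), abs=1e-9
            )
            assert -1.0 - 1e-12 <= rep.si <= 1.0 + 1e-12
            assert rep.dbi >= 0.0


class TestDispatch:
    @pytest.mark.parametrize("algorithm", ["KM", "HC", "EM"])
    def test_uniform_signature(self, benchmark_features, algorithm):
        a = cluster_features(benchmark_features, 5, algorithm=algorithm, seed=0)
        assert a.algorithm == algorithm
        assert len(a.labels) == benchmark_features.n_rows

    def test_unknown_algorithm_rejected(self, benchmark_features):
        with pytest.raises(ValueError):
            cluster_features(benchmark_features, 3, algorithm="DBSCAN")
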