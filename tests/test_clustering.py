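import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibench import clustering as cl


class TestPcaReduce:
    def test_planar_data_needs_two_components(self, rng):
        basis = rng.standard_normal((2, 121))
        coords = rng.standard_normal((300, 2)) * [5.0, 2.0]
        X = coords @ basis + rng.standard_normal((300, 121)) * 1e-5 + 3.0
        emb = cl.pca_reduce(X, variance_target=0.99)
        assert emb.n_components == 2

    def test_full_retention_keeps_all_components(self, rng):
        X = rng.standard_normal((40, 121))
        emb = cl.pca_reduce(X, variance_target=1.0)
        assert emb.n_components == min(40 - 1, 121)

    def test_reconstruction_bounded_by_discarded_variance(self, small_cohort_beats):
        X = small_cohort_beats.beats
        emb = cl.pca_reduce(X, variance_target=0.99)
        recon = emb.inverse_transform(emb.coords)
        centered_energy = np.sum((X - X.mean(axis=0)) ** 2)
        assert np.sum((X - recon) ** 2) <= 0.01 * centered_energy

    def test_degenerate_identical_beats_rejected(self):
        X = np.ones((10, 121))
        with pytest.raises(ValueError):
            cl.pca_reduce(X)


class TestKmeansBest:
    def test_separated_blobs_recovered_exactly(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]], dtype=float)
        labels = np.repeat([0, 1, 2], 100)
        X = centers[labels] + rng.standard_normal((300, 2))
        res = cl.kmeans_best(X, K=3, seed=0)
        res = cl.score_clusters(res, labels)
        assert res.metrics["accuracy"] == 1.0

    def test_single_cluster_centroid_is_mean(self, rng):
        X = rng.standard_normal((50, 4))
        res = cl.kmeans_best(X, K=1, seed=0)
        assert np.allclose(res.centroids[0], X.mean(axis=0))

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((120, 5))
        a = cl.kmeans_best(X, K=4, seed=9)
        b = cl.kmeans_best(X, K=4, seed=9)
        assert np.array_equal(a.cluster_labels, b.cluster_labels)
        assert np.allclose(a.centroids, b.centroids)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.kmeans_best(rng.standard_normal((5, 2)), K=6)


class TestMunkresMap:
    def test_identity_labels_map_identically(self):
        y = np.array([0, 1, 2] * 30)
        mapping = cl.munkres_map(y, y)
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_permuted_labels_invert_the_permutation(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 200)
        perm = {0: 2, 1: 0, 2: 1}
        clusters = np.array([perm[v] for v in y])
        mapping = cl.munkres_map(y, clusters)
        oracle = cl.munkres_map_bruteforce(y, clusters)
        assert mapping == oracle
        assert mapping == {2: 0, 0: 1, 1: 2}  # inverse of perm

    def test_tie_goes_to_lowest_cluster_index(self):
        # clusters 0 and 1 tie on class 0 (5 co-occurrences each);
        # both assignments have equal total cost
        y = np.array([0] * 5 + [1] * 3 + [0] * 5 + [1] * 3)
        c = np.array([0] * 8 + [1] * 8)
        mapping = cl.munkres_map(y, c)
        assert mapping[0] == 0  # lowest cluster index wins the tied class
        assert mapping[1] == 1

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_classes = int(rng.integers(2, 7))
            n = int(rng.integers(20, 120))
            y = rng.integers(0, n_classes, n)
            c = rng.integers(0, n_classes, n)
            mapping = cl.munkres_map(y, c)
            oracle = cl.munkres_map_bruteforce(y, c)
            # scores must agree (mappings may differ only among exact ties)
            score = sum(int(((y == mapping[k]) & (c == k)).sum())
                        for k in mapping if mapping[k] != -1)
            score_oracle = sum(int(((y == oracle[k]) & (c == k)).sum())
                               for k in oracle if oracle[k] != -1)
            assert score == score_oracle

    def test_extra_clusters_left_unmapped(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        c = np.array([0, 0, 1, 1, 2, 2])
        mapping = cl.munkres_map(y, c)
        assert sorted(v for v in mapping.values() if v != -1) == [0, 1]
        assert -1 in mapping.values()

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            cl.munkres_map(np.array([]), np.array([]))


class TestClusteringMetrics:
    def test_printed_lead_identification_values(self):
        y = np.zeros(1000, dtype=int)
        yhat = y.copy()
        yhat[:238] = 1  # 762 correct
        m = cl.clustering_metrics(y, yhat)
        assert round(m["accuracy"], 3) == 0.762
        assert round(m["micro_f1"], 3) == 0.865

    def test_perfect_prediction(self):
        y = np.arange(50) % 3
        m = cl.clustering_metrics(y, y)
        assert m["accuracy"] == 1.0 and m["micro_f1"] == 1.0

    def test_per_class_macro_form(self):
        # N=4, C=2, TP=(2,1): macro = (2*2/6 + 2*1/5)/2
        y = np.array([0, 0, 1, 1])
        yhat = np.array([0, 0, 1, 0])
        m = cl.clustering_metrics(y, yhat)
        assert m["macro_f1"] == pytest.approx((2 * 2 / 6 + 2 * 1 / 5) / 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=1, max_size=200))
    def test_micro_f1_identity(self, pairs):
        """micro-F1 = 2a/(1+a) for accuracy a, on arbitrary label sets."""
        y = np.array([p[0] for p in pairs])
        yhat = np.array([p[1] for p in pairs])
        m = cl.clustering_metrics(y, yhat)
        a = m["accuracy"]
        assert m["micro_f1"] == pytest.approx(2 * a / (1 + a))

    def test_standard_macro_differs_from_aggregate_form(self):
        y = np.array([0] * 90 + [1] * 10)
        yhat = np.array([0] * 80 + [1] * 10 + [1] * 10)
        m = cl.clustering_metrics(y, yhat, standard_macro=True)
        assert "macro_f1_standard" in m
        assert m["macro_f1_standard"] != pytest.approx(m["macro_f1"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cl.clustering_metrics(np.array([]), np.array([]))


class TestCentroidHeartbeats:
    def test_pure_cluster_centroid_recovers_mean_beat(self, small_cohort_beats):
        X = small_cohort_beats.beats[:200]
        emb = cl.pca_reduce(X, variance_target=0.999)
        sub = emb.coords[:50]
        centroid = sub.mean(axis=0)
        res = cl.ClusterResult(centroids=centroid[None, :],
                               cluster_labels=np.zeros(50, dtype=int))
        wave = cl.centroid_heartbeats(res, emb)[0]
        mean_beat = X[:50].mean(axis=0)
        scale = np.abs(X).max()
        assert np.max(np.abs(wave - mean_beat)) < 0.05 * scale

    def test_zero_centroid_gives_embedding_mean(self, rng):
        X = rng.standard_normal((60, 121)) + 2.0
        emb = cl.pca_reduce(X, variance_target=0.95)
        res = cl.ClusterResult(centroids=np.zeros((1, emb.n_components)),
                               cluster_labels=np.zeros(60, dtype=int))
        wave = cl.centroid_heartbeats(res, emb)[0]
        assert np.allclose(wave, emb.mean)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((60, 121))
        emb = cl.pca_reduce(X, variance_target=0.9)
        res = cl.ClusterResult(centroids=np.zeros((1, emb.n_components + 1)),
                               cluster_labels=np.zeros(60, dtype=int))
        with pytest.raises(ValueError):
            cl.centroid_heartbeats(res, emb)


class TestTsne:
    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((120, 10))
        a = cl.tsne_project(X, perplexity=20, seed=4)
        b = cl.tsne_project(X, perplexity=20, seed=4)
        assert np.allclose(a, b)

    def test_separated_blobs_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score
        labels = np.repeat([0, 1], 100)
        X = np.vstack([rng.standard_normal((100, 8)),
                       rng.standard_normal((100, 8)) + 25.0])
        emb = cl.tsne_project(X, perplexity=30, seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.tsne_project(rng.standard_normal((10, 3)), perplexity=30)
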