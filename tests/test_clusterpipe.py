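import numpy as np
import pandas as pd
import pytest

from hemigait import clusterpipe as cp
from hemigait.clusterpipe import ClusterError
from hemigait.markerio import ParticipantMeta


class TestZScore:
    def test_hand_case(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 20.0, 0.0]})
        scaled, mean, sd = cp.zscore_scale(table)
        np.testing.assert_allclose(scaled["a"], [-1.0, 0.0, 1.0])
        assert sd["a"] == pytest.approx(1.0)  # sample sd, n-1 denominator

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once, _, _ = cp.zscore_scale(table)
        twice, _, _ = cp.zscore_scale(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ClusterError, match="zero-variance"):
            cp.zscore_scale(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]}))

    def test_missing_cells_rejected(self):
        with pytest.raises(ClusterError, match="missing"):
            cp.zscore_scale(pd.DataFrame({"a": [1.0, np.nan, 3.0]}))


class TestKMeans:
    def test_separated_pairs_recovered(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, centroids = cp.kmeans_fit(X, 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_duplicate_rows_only_raises_empty_cluster(self):
        X = np.tile([[1.0, 2.0]], (6, 1))
        with pytest.raises(ClusterError, match="distinct"):
            cp.kmeans_fit(X, 2, seed=0)

    def test_same_seed_gives_identical_labels(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        l1, c1 = cp.kmeans_fit(X, 3, seed=7)
        l2, c2 = cp.kmeans_fit(X, 3, seed=7)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(c1, c2)

    def test_labels_canonicalized_by_size(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(8, 0.1, (10, 2))])
        labels, _ = cp.kmeans_fit(X, 2, seed=0)
        assert (labels == 0).sum() == 30  # label 0 = largest cluster


class TestClusterSS:
    def test_hand_configuration(self):
        """Points (0,0),(0,2) | (4,0),(4,2): WSS = 4 total, BSS = 16."""
        X = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])
        labels = np.array([0, 0, 1, 1])
        wss, total, bss = cp.cluster_ss(X, labels)
        np.testing.assert_allclose(wss, [2.0, 2.0])
        assert total == pytest.approx(4.0)
        assert bss == pytest.approx(16.0)

    def test_singleton_clusters_have_zero_wss(self):
        X = np.array([[0.0], [5.0]])
        wss, total, _ = cp.cluster_ss(X, np.array([0, 1]))
        assert total == 0.0

    def test_tss_decomposition_identity_on_random_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 7))
        labels, _ = cp.kmeans_fit(X, 4, seed=2)
        wss, total, bss = cp.cluster_ss(X, labels)
        tss = float(((X - X.mean(axis=0)) ** 2).sum())
        assert total + bss == pytest.approx(tss, abs=1e-8)


class TestSilhouetteSelection:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_equally_separated_blobs_select_true_k(self, n_blobs):
        rng = np.random.default_rng(0)
        # simplex corners: every pair of centres 12 units apart (sd = 1)
        centers = np.zeros((n_blobs, 7))
        for i in range(n_blobs):
            centers[i, i] = 12.0 / np.sqrt(2)
        X = np.vstack([rng.normal(c, 1.0, (15, 7)) for c in centers])
        chosen, profile = cp.select_k_silhouette(X, seed=0)
        assert chosen == n_blobs
        assert set(profile) == set(range(2, 9))


class TestImportance:
    def test_informative_feature_ranked_first_noise_near_zero(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 7))
        labels = (X[:, 0] > 0).astype(int)
        imp = cp.rf_importance(pd.DataFrame(X, columns=[f"m{j}" for j in range(7)]),
                               labels, n_trees=300, seed=0)
        assert imp.index[0] == "m0"
        assert np.all(np.abs(imp.drop("m0")) <= 0.02)

    def test_permuting_informative_feature_never_helps(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 4))
        labels = (X[:, 1] + 0.3 * rng.normal(size=80) > 0).astype(int)
        imp = cp.rf_importance(X, labels, n_trees=200, seed=3)
        assert np.all(imp >= -0.02)

    def test_cloned_informative_features_share_importance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        X = np.column_stack([base, base, rng.normal(size=(100, 3))])
        labels = (base > 0).astype(int)
        imp = cp.rf_importance(X, labels, n_trees=300, seed=0)
        assert imp["x0"] > 0.01 and imp["x1"] > 0.01

    def test_tiny_cluster_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        labels = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ClusterError, match=">= 3 members"):
            cp.rf_importance(X, labels)


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(-1, 1, 20)
        X = np.outer(t, [1.0, 2.0, -1.0])
        scores, explained = cp.pca_project(X)
        assert explained[0] == pytest.approx(1.0)

    def test_full_projection_is_isometric(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 5))
        from sklearn.decomposition import PCA

        full = PCA(n_components=5, svd_solver="full").fit_transform(X - X.mean(0))
        d_in = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_out = np.linalg.norm(full[:, None] - full[None, :], axis=2)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_isotropic_gaussian_spreads_variance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(600, 7))
        _, explained = cp.pca_project(X)
        assert np.all(np.abs(explained - 1 / 7) < 0.05)


class TestCompareConditions:
    def _result(self, labels, centroids, ids, condition, bss=10.0):
        k = len(centroids)
        return cp.ClusterResult(
            condition=condition, participant_ids=list(ids),
            labels=np.asarray(labels), centroids=np.asarray(centroids, float),
            wss_per_cluster=np.ones(k), total_wss=float(k), bss=bss,
            silhouette_by_k={2: 0.5}, chosen_k=k,
            importance=pd.Series(dtype=float), pca_scores=np.zeros((len(ids), 2)),
            pca_explained=np.array([0.5, 0.3]),
            scaling_mean=pd.Series(dtype=float), scaling_sd=pd.Series(dtype=float),
        )

    def test_identical_labelings_give_zero_switchers(self):
        ids = list("abcdef")
        a = self._result([0, 0, 0, 1, 1, 1], [[0.0, 0.0], [4.0, 4.0]], ids, "self_selected")
        b = self._result([0, 0, 0, 1, 1, 1], [[0.1, 0.1], [4.1, 4.1]], ids, "fast")
        rep = cp.compare_conditions(a, b)
        assert rep["n_switchers"] == 0

    def test_label_permutation_resolved_by_centroid_matching(self):
        ids = list("abcdef")
        a = self._result([0, 0, 0, 1, 1, 1], [[0.0, 0.0], [4.0, 4.0]], ids, "self_selected")
        # same partition, labels swapped, centroids swapped accordingly
        b = self._result([1, 1, 1, 0, 0, 0], [[4.0, 4.0], [0.0, 0.0]], ids, "fast")
        rep = cp.compare_conditions(a, b)
        assert rep["n_switchers"] == 0

    def test_single_boundary_crossing_reported(self):
        ids = list("abcdef")
        a = self._result([0, 0, 0, 1, 1, 1], [[0.0, 0.0], [4.0, 4.0]], ids, "self_selected")
        b = self._result([0, 0, 1, 1, 1, 1], [[0.0, 0.0], [4.0, 4.0]], ids, "fast")
        rep = cp.compare_conditions(a, b)
        assert rep["n_switchers"] == 1 and rep["switchers"] == ["c"]

    def test_mismatched_sets_restricted_to_intersection(self):
        a = self._result([0, 0, 1, 1], [[0.0], [4.0]], list("abcd"), "self_selected")
        b = self._result([0, 1, 1], [[0.0], [4.0]], list("bcd"), "fast")
        rep = cp.compare_conditions(a, b)
        assert "common participants" in rep["note"]
        assert set(rep["assignments"].index) == set("bcd")


class TestClinicalContrast:
    def _metas(self, values_by_cluster):
        metas, labels = [], {}
        i = 0
        for cluster, values in values_by_cluster.items():
            for v in values:
                pid = f"S{i:02d}"
                metas.append(ParticipantMeta(pid, "stroke", "left", 60.0, [0.8],
                                             le_fugl_meyer=int(v)))
                labels[pid] = cluster
                i += 1
        return pd.Series(labels), metas

    def test_exact_enumeration_hand_case(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/C(6,3) = 0.10."""
        labels, metas = self._metas({0: [1, 2, 3], 1: [4, 5, 6]})
        res = cp.clinical_contrast(labels, metas, "le_fugl_meyer")
        assert min(res["U"], 9 - res["U"]) == 0
        assert res["p"] == pytest.approx(0.10)
        assert res["method"] == "exact"

    def test_symmetric_configuration_gives_p_one(self):
        labels, metas = self._metas({0: [1, 4], 1: [2, 3]})
        res = cp.clinical_contrast(labels, metas, "le_fugl_meyer")
        assert res["p"] == pytest.approx(1.0)

    def test_identical_values_rejected(self):
        labels, metas = self._metas({0: [5, 5], 1: [5, 5]})
        with pytest.raises(ClusterError, match="identical"):
            cp.clinical_contrast(labels, metas, "le_fugl_meyer")

    def test_shifted_groups_detected_at_moderate_sample(self):
        """1.5-sd shift, n = 12 per subgroup: Mann-Whitney detects it."""
        rng = np.random.default_rng(8)
        lo = np.clip(np.round(rng.normal(18, 4, 12)), 0, 34)
        hi = np.clip(np.round(rng.normal(24, 4, 12)), 0, 34)
        labels, metas = self._metas({1: lo, 0: hi})
        res = cp.clinical_contrast(labels, metas, "le_fugl_meyer")
        assert res["p"] < 0.05
        assert res["medians"][1] < res["medians"][0]  # impaired cluster lower FM

    def test_speed_variable_uses_slowest_speed(self):
        labels, metas = self._metas({0: [20, 21, 22], 1: [23, 24, 25]})
        for m, s in zip(metas, ([0.5, 1.0], [0.6, 1.1], [0.7, 0.9],
                                [0.9, 1.2], [1.0, 1.4], [1.1, 1.5])):
            m.speeds = list(s)
        res = cp.clinical_contrast(labels, metas, "speed")
        assert res["p"] == pytest.approx(0.10)  # slowest speeds fully separated
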