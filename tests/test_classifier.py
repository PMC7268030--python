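"""Supervised stage: t maps, t0 selection, kernel PCA, FLD, voting."""

import numpy as np
import pytest
from scipy import stats

from icalearn import (
    ClassifierConfig,
    GroupSummary,
    fit_fld,
    fit_kpca,
    majority_vote,
    predict_subject,
    select_threshold,
    t_from_summary,
    threshold_features,
    train_ensemble,
    voxel_t_map,
)
from icalearn.classifier import feature_voxels, fisher_separation


def _labels(n_sz, n_hc):
    return np.array(["SZ"] * n_sz + ["HC"] * n_hc)


class TestVoxelTMap:
    def test_equal_means_give_zero_t(self):
        X = np.array([[1.0, 5.0], [3.0, 7.0], [0.0, 4.0], [4.0, 8.0]])
        t, zero = voxel_t_map(X, _labels(2, 2))
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert not zero.any()

    def test_hand_computed_value(self):
        # SZ voxel values {1, 3}, HC {2, 4}: pooled SD sqrt(2), t = -1/sqrt(2)
        X = np.array([[1.0], [3.0], [2.0], [4.0]])
        t, _ = voxel_t_map(X, _labels(2, 2))
        assert t[0] == pytest.approx(-0.707, abs=1e-3)

    def test_matches_summary_statistic_formula(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 30))
        labels = _labels(5, 7)
        t, _ = voxel_t_map(X, labels)
        for v in range(30):
            a = GroupSummary("SZ", 5, X[:5, v].mean(), X[:5, v].std(ddof=1))
            b = GroupSummary("HC", 7, X[5:, v].mean(), X[5:, v].std(ddof=1))
            expected, _, _ = t_from_summary(a, b)
            assert t[v] == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 20))
        labels = _labels(8, 7)
        t, _ = voxel_t_map(X, labels)
        ref = stats.ttest_ind(X[:8], X[8:], axis=0, equal_var=True).statistic
        np.testing.assert_allclose(t, ref, atol=1e-10)

    def test_zero_variance_voxels_flagged(self):
        X = np.ones((6, 3))
        X[:, 1] = np.arange(6)
        t, zero = voxel_t_map(X, _labels(3, 3))
        assert zero[0] and zero[2] and not zero[1]
        assert t[0] == 0.0

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            voxel_t_map(np.zeros((3, 4)), np.array(["SZ", "HC", "HC"]))


class TestThresholdFeatures:
    def test_zero_threshold_keeps_all(self):
        t_map = np.array([0.5, -1.5, 2.5])
        out = threshold_features(np.arange(3.0), t_map, 0.0)
        assert out.shape == (3,)

    def test_counting(self):
        t_map = np.array([0.5, 1.5, 2.5])
        out = threshold_features(np.arange(3.0), t_map, 1.0)
        np.testing.assert_array_equal(out, [1.0, 2.0])

    def test_threshold_above_max_raises(self):
        with pytest.raises(ValueError, match="no voxels"):
            threshold_features(np.arange(3.0), np.array([0.5, 1.5, 2.5]), 2.5)


class TestKPCA:
    def test_linear_kernel_equals_pca_scores(self):
        """Linear-kernel kPCA training scores match an ordinary PCA computed
        via an independent covariance eigendecomposition, axis by axis."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 10)) * np.linspace(1, 4, 10)
        model = fit_kpca(X, kernel="linear", d=4)
        scores = model.project(X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        pca_scores = Xc @ evecs[:, ::-1][:, :4]
        for j in range(4):
            c = np.corrcoef(scores[:, j], pca_scores[:, j])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_reference(self):
        from sklearn.decomposition import KernelPCA

        rng = np.random.default_rng(3)
        X, Xt = rng.standard_normal((20, 8)), rng.standard_normal((6, 8))
        model = fit_kpca(X, kernel="rbf", d=5, gamma=0.2)
        ref = KernelPCA(n_components=5, kernel="rbf", gamma=0.2, eigen_solver="dense")
        ref_scores = ref.fit(X).transform(Xt)
        scores = model.project(Xt)
        for j in range(5):
            c = np.corrcoef(scores[:, j], ref_scores[:, j])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-8)

    def test_centered_kernel_rows_sum_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 6))
        model = fit_kpca(X, kernel="rbf", d=3)
        from icalearn.classifier import _kernel_matrix

        K = _kernel_matrix("rbf", model.gamma, X, X)
        Kc = (
            K
            - K.mean(axis=0)[None, :]
            - K.mean(axis=1)[:, None]
            + K.mean()
        )
        np.testing.assert_allclose(Kc.sum(axis=1), 0.0, atol=1e-8)

    def test_out_of_sample_equals_in_sample_for_training_points(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((18, 7))
        model = fit_kpca(X, kernel="rbf", d=4)
        all_at_once = model.project(X)
        one_by_one = np.vstack([model.project(x) for x in X])
        np.testing.assert_allclose(all_at_once, one_by_one, atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(6)
        model = fit_kpca(rng.standard_normal((12, 5)), kernel="rbf", d=6)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_d_exceeding_n_minus_one_raises(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="exceeds N-1"):
            fit_kpca(rng.standard_normal((5, 8)), d=5)

    def test_d_exceeding_rank_raises(self):
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10)  # rank-1 centered data
        with pytest.raises(ValueError, match="rank"):
            fit_kpca(X, kernel="linear", d=3)


class TestFLD:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(5, 0.3, (10, 2)), rng.normal(-5, 0.3, (10, 2))])
        labels = _labels(10, 10)
        model = fit_fld(X, labels)
        preds = [model.predict(x)[0] for x in X]
        assert np.mean(np.asarray(preds) == labels) == 1.0

    def test_null_training_accuracy_near_chance(self):
        """With identical class means, mean FLD training accuracy over
        random draws stays in a chance band."""
        rng = np.random.default_rng(9)
        accs = []
        for _ in range(100):
            X = rng.standard_normal((40, 2))
            labels = _labels(20, 20)
            model = fit_fld(X, labels)
            preds = np.array([model.predict(x)[0] for x in X])
            accs.append(np.mean(preds == labels))
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_training_predictions_affine_invariant(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(2, 1, (12, 3)), rng.normal(-2, 1, (12, 3))])
        labels = _labels(12, 12)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        m1 = fit_fld(X, labels, ridge=1e-12)
        m2 = fit_fld(X @ A.T + b, labels, ridge=1e-12)
        p1 = [m1.predict(x)[0] for x in X]
        p2 = [m2.predict(x @ A.T + b)[0] for x in X]
        assert p1 == p2

    def test_degenerate_projections_warn_and_yield_chance_model(self):
        X = np.ones((8, 2))
        with pytest.warns(RuntimeWarning, match="identical"):
            model = fit_fld(X, _labels(4, 4))
        assert model.degenerate
        assert model.predict(np.ones(2))[0] == "HC"  # zero score resolves to HC


class TestSelectThreshold:
    def test_single_candidate_grid_returns_it(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((16, 50))
        X[:8] += 1.0
        cfg = ClassifierConfig(d=3, t0_percentiles=(50,))
        t_map, _ = voxel_t_map(X, _labels(8, 8))
        t0, trace = select_threshold(X, _labels(8, 8), config=cfg, t_map=t_map)
        assert t0 == pytest.approx(np.percentile(np.abs(t_map), 50))
        assert len(trace) == 1

    def test_returned_t0_maximizes_trace(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 80))
        X[:10, :10] += 1.5
        cfg = ClassifierConfig(d=4, t0_percentiles=(50, 60, 70, 80, 90))
        t0, trace = select_threshold(X, _labels(10, 10), config=cfg)
        best_j = max(j for _, j in trace)
        selected_j = dict(trace)[t0]
        assert selected_j == best_j
        # ties go to the smaller t0
        assert t0 == min(c for c, j in trace if j == best_j)

    def test_recovers_planted_voxels_at_high_snr(self):
        """With a strong effect confined to a known voxel subset, the
        selected feature set recovers >= 90% of planted voxels on average."""
        rng = np.random.default_rng(13)
        V, planted = 200, 20
        cfg = ClassifierConfig(d=5, t0_percentiles=tuple(range(50, 100)))
        fractions = []
        for _ in range(50):
            X = rng.standard_normal((30, V))
            X[:15, :planted] += 3.0
            labels = _labels(15, 15)
            t_map, _ = voxel_t_map(X, labels)
            t0, _ = select_threshold(X, labels, config=cfg, t_map=t_map)
            keep = set(feature_voxels(t_map, t0).tolist())
            fractions.append(len(keep & set(range(planted))) / planted)
        assert np.mean(fractions) >= 0.9

    def test_infeasible_grid_raises(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((12, 10))
        cfg = ClassifierConfig(d=9, t0_percentiles=(99,))  # leaves < d+1 voxels
        with pytest.raises(ValueError, match="feasible"):
            select_threshold(X, _labels(6, 6), config=cfg)


class TestMajorityVote:
    def test_strict_majority(self):
        votes = ["SZ"] * 9 + ["HC"] * 7
        assert majority_vote(votes, [0.0] * 16, [1.0] * 16) == "SZ"

    def test_tie_resolved_by_normalized_score_sum(self):
        votes = ["SZ"] * 8 + ["HC"] * 8
        scores = [0.3 / 16] * 16
        assert majority_vote(votes, scores, [1.0] * 16) == "SZ"
        assert majority_vote(votes, [-s for s in scores], [1.0] * 16) == "HC"
        assert majority_vote(votes, [0.0] * 16, [1.0] * 16) == "HC"  # exact zero

    def test_unanimous(self):
        assert majority_vote(["HC"] * 16, [0.1] * 16, [1.0] * 16) == "HC"


class TestEnsemble:
    def _planted_maps(self, rng, n=20, V=120, K=6, strong=3, shift=2.0):
        maps = rng.standard_normal((K, n, V))
        for k in range(strong):
            maps[k, : n // 2, :15] += shift
        return maps, _labels(n // 2, n // 2)

    def test_training_accuracy_with_planted_effect(self):
        rng = np.random.default_rng(15)
        maps, labels = self._planted_maps(rng)
        cfg = ClassifierConfig(d=4, t0_percentiles=(50, 70, 90))
        ens = train_ensemble(maps, labels, config=cfg)
        preds = [
            predict_subject(ens, maps[:, i, :], subject_id=str(i)).final
            for i in range(maps.shape[1])
        ]
        assert np.mean(np.asarray(preds) == labels) >= 0.9

    def test_single_class_labels_raise(self):
        rng = np.random.default_rng(16)
        maps = rng.standard_normal((2, 8, 30))
        with pytest.raises(ValueError, match="single class"):
            train_ensemble(maps, np.array(["HC"] * 8))

    def test_subject_order_invariance(self):
        from icalearn import ensemble_digest

        rng = np.random.default_rng(17)
        maps, labels = self._planted_maps(rng, n=14, V=80, K=3, strong=2)
        cfg = ClassifierConfig(d=3, t0_percentiles=(50, 70, 90))
        ens1 = train_ensemble(maps, labels, config=cfg)
        perm = rng.permutation(14)
        ens2 = train_ensemble(maps[:, perm, :], labels[perm], config=cfg)
        # same t maps and thresholds; kPCA training rows are permuted, so
        # compare the parameters that must be order-free
        for a, b in zip(ens1.classifiers, ens2.classifiers):
            np.testing.assert_allclose(a.t_map, b.t_map, atol=1e-10)
            assert a.t0 == pytest.approx(b.t0)
            np.testing.assert_array_equal(a.feature_voxel_idx, b.feature_voxel_idx)

    def test_per_component_null_accuracy_calibrated_under_permutation(self):
        """On null data with permuted labels, held-out per-component accuracy
        distributes around chance."""
        rng = np.random.default_rng(18)
        cfg = ClassifierConfig(d=3, t0_percentiles=(50, 70, 90))
        accs = []
        for _ in range(200):
            train = rng.standard_normal((1, 16, 60))
            test = rng.standard_normal((1, 10, 60))
            labels = rng.permutation(_labels(8, 8))
            test_labels = _labels(5, 5)
            ens = train_ensemble(train, labels, config=cfg)
            preds = [
                predict_subject(ens, test[:, i, :]).final for i in range(10)
            ]
            accs.append(np.mean(np.asarray(preds) == test_labels))
        assert abs(np.mean(accs) - 0.5) <= 0.1


def test_fisher_separation_definition():
    s = np.array([2.0, 2.1, 1.9, -2.0, -2.1, -1.9])
    labels = _labels(3, 3)
    j = fisher_separation(s, labels)
    expected = (2.0 - (-2.0)) ** 2 / (0.01 + 0.01)
    assert j == pytest.approx(expected)
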