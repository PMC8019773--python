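import numpy as np
import pytest

from hfpef_risk.config import KernelConfig
from hfpef_risk.kpls import (
    center_test_kernel,
    center_train_kernel,
    fit_kpls,
    gaussian_kernel,
    predict_features,
    predict_kpls,
    train_kpls,
)


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert gaussian_kernel(x, x, sigma=0.7)[0, 0] == pytest.approx(1.0)

    def test_formula_at_known_distance(self):
        sigma = 1.3
        a = np.array([[0.0]])
        b = np.array([[np.sqrt(2.0) * sigma]])  # ||a-b||^2 = 2 sigma^2
        assert gaussian_kernel(a, b, sigma)[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_huge_sigma_limit(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(5, 3))
        K = gaussian_kernel(X, X, sigma=1e8)
        assert np.all(np.abs(K - 1.0) < 1e-6)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 4))
        K = gaussian_kernel(X, X, sigma=1.0)
        assert np.all(K > 0) and np.all(K <= 1.0 + 1e-15)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)

    def test_invalid_inputs(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="sigma"):
            gaussian_kernel(X, X, sigma=0.0)
        with pytest.raises(ValueError, match="mismatch"):
            gaussian_kernel(X, np.zeros((3, 4)), sigma=1.0)


class TestCentering:
    def test_all_ones_centers_to_zero(self):
        K = np.ones((6, 6))
        np.testing.assert_allclose(center_train_kernel(K), 0.0, atol=1e-12)

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 10))
        K = A @ A.T
        Kc = center_train_kernel(K)
        np.testing.assert_allclose(Kc.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Kc.sum(axis=1), 0.0, atol=1e-8)

    def test_centering_idempotent_on_centered_linear_kernel(self):
        # linear kernel of column-centered X is already feature-space centered
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        Xc = X - X.mean(axis=0)
        K = Xc @ Xc.T
        np.testing.assert_allclose(center_train_kernel(K), K, atol=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            center_train_kernel(np.ones((3, 4)))

    def test_test_centering_consistent_with_train(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 3))
        K = gaussian_kernel(X, X, 1.1)
        Kc = center_train_kernel(K)
        # feeding training rows through the test path reproduces Kc rows
        Kc_test = center_test_kernel(K, K)
        np.testing.assert_allclose(Kc_test, Kc, atol=1e-10)

    def test_all_ones_test_kernel(self):
        K = np.ones((5, 5))
        np.testing.assert_allclose(center_test_kernel(np.ones((2, 5)), K), 0.0, atol=1e-12)

    def test_single_test_point_shape(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 2))
        K = gaussian_kernel(X, X, 1.0)
        kt = gaussian_kernel(X[:1], X, 1.0)
        assert center_test_kernel(kt, K).shape == (1, 7)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            center_test_kernel(np.ones((2, 4)), np.ones((5, 5)))


class TestFitPredict:
    def test_separable_clusters_perfect_at_one_component(self, separable_clusters):
        X, y = separable_clusters
        model = train_kpls(X, y, KernelConfig(sigma=1.0, n_components=1))
        _, labels = predict_features(model, X)
        assert np.array_equal(labels, y)

    def test_constant_y_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        K = center_train_kernel(gaussian_kernel(X, X, 1.0))
        with pytest.raises(ValueError, match="zero variance"):
            fit_kpls(K, np.ones(10), KernelConfig(sigma=1.0))

    def test_linear_kernel_matches_linear_pls(self):
        # primal-dual equivalence: KPLS with the linear kernel reproduces
        # classical NIPALS PLS fitted values
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        for n, p, a in [(20, 6, 3), (30, 10, 5), (15, 4, 2)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xc = X - X.mean(axis=0)
            Kc = center_train_kernel(Xc @ Xc.T)
            model = fit_kpls(Kc, y, KernelConfig(sigma=1.0, n_components=a))
            mine, _ = predict_kpls(model, Kc)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_scores_orthogonal(self, spherical_data):
        X, y = spherical_data(seed=8)
        model = train_kpls(X, y, KernelConfig(sigma=1.0, n_components=4))
        T = model.scores
        gram = T.T @ T
        np.testing.assert_allclose(gram, np.eye(T.shape[1]), atol=1e-8)

    def test_training_r2_monotone_in_components(self, spherical_data):
        X, y = spherical_data(seed=9)
        K = gaussian_kernel(X, X, 1.0)
        Kc = center_train_kernel(K)
        r2 = []
        for a in range(1, 6):
            m = fit_kpls(Kc, y, KernelConfig(sigma=1.0, n_components=a))
            fitted, _ = predict_kpls(m, Kc)
            ss_res = ((y - fitted) ** 2).sum()
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2.append(1 - ss_res / ss_tot)
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_training_points_reproduce_fitted_labels(self, separable_clusters):
        X, y = separable_clusters
        model = train_kpls(X, y, KernelConfig(sigma=1.0, n_components=2))
        fit_scores, fit_labels = predict_kpls(model, model.K_train)
        test_scores, test_labels = predict_features(model, X)
        np.testing.assert_allclose(test_scores, fit_scores, atol=1e-10)
        assert np.array_equal(test_labels, fit_labels)

    def test_midpoint_scores_near_half(self, separable_clusters):
        # equidistant from two balanced clusters -> response near the midpoint
        X, y = separable_clusters
        model = train_kpls(X, y, KernelConfig(sigma=2.0, n_components=1))
        mid = np.array([[5.0, 5.0]])
        score, _ = predict_features(model, mid)
        assert abs(score[0] - 0.5) < 0.1

    def test_extreme_threshold_labels_everything_positive(self, separable_clusters):
        X, y = separable_clusters
        model = train_kpls(X, y, KernelConfig(sigma=1.0, n_components=1, threshold=-1e9))
        _, labels = predict_features(model, X)
        assert np.all(labels == 1)

    def test_prediction_invariant_to_training_permutation(self, spherical_data):
        X, y = spherical_data(seed=10)
        X_test = np.random.default_rng(11).normal(size=(8, 3))
        m1 = train_kpls(X, y, KernelConfig(sigma=1.2, n_components=3))
        s1, _ = predict_features(m1, X_test)
        perm = np.random.default_rng(12).permutation(len(y))
        m2 = train_kpls(X[perm], y[perm], KernelConfig(sigma=1.2, n_components=3))
        s2, _ = predict_features(m2, X_test)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_requested_components_beyond_rank_stop_early(self, caplog):
        # rank-1 data: only one meaningful component exists
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        Xc = X - X.mean(axis=0)
        Kc = center_train_kernel(Xc @ Xc.T)
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            m = fit_kpls(Kc, y, KernelConfig(sigma=1.0, n_components=3))
        assert m.n_components < 3


def test_kpls_beats_logistic_on_radial_structure(spherical_data):
    """Holdout AUC of Gaussian KPLS strictly exceeds logistic regression's on
    spherical-boundary data (paired Wilcoxon over 50 draws)."""
    from scipy.stats import wilcoxon
    from sklearn.linear_model import LogisticRegression

    from hfpef_risk.evaluation import auc_rank

    diffs = []
    for rep in range(50):
        X, y = spherical_data(n_good=270, n_poor=130, seed=100 + rep)
        n_train = 320
        Xtr, ytr, Xte, yte = X[:n_train], y[:n_train], X[n_train:], y[n_train:]
        model = train_kpls(Xtr, ytr, KernelConfig(sigma=1.0, n_components=3))
        s_kpls, _ = predict_features(model, Xte)
        lr = LogisticRegression(max_iter=1000).fit(Xtr, ytr)
        s_lr = lr.predict_proba(Xte)[:, 1]
        diffs.append(auc_rank(yte, s_kpls) - auc_rank(yte, s_lr))
    assert np.mean(diffs) > 0.2  # materially better, not marginal
    assert wilcoxon(diffs, alternative="greater").pvalue < 0.01
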