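"""Fisher-LDA machine-observer tests against independent oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from shadowedge import lda


def gaussian_data(rng, mu0, mu1, cov, n0, n1):
    x0 = rng.multivariate_normal(mu0, cov, size=n0)
    x1 = rng.multivariate_normal(mu1, cov, size=n1)
    X = np.vstack([x0, x1])
    y = np.array(["shadow"] * n0 + ["other"] * n1)
    return X, y


class TestFit:
    def test_identity_covariance_algebra(self, rng):
        # mu0 = (0,0), mu1 = (1,0), Sigma = I: w = (1,0), c = -1/2,
        # decision boundary at s1 = 1/2
        X, y = gaussian_data(rng, [0, 0], [1, 0], 0.0001 * np.eye(2), 500, 500)
        # force the exact moments by centering each class
        X[:500] -= X[:500].mean(axis=0)
        X[500:] += np.array([1, 0]) - X[500:].mean(axis=0)
        m = lda.fit_lda(X, y, ridge_scale=0.0)
        sigma_inv = np.linalg.inv(m.sigma)
        np.testing.assert_allclose(m.w, sigma_inv @ (m.mu1 - m.mu0), atol=1e-9)
        # with near-zero sample covariance Sigma ~ eps*I; check the exact-I case
        m2 = lda.LDAModel(
            mu0=np.zeros(2), mu1=np.array([1.0, 0]), sigma=np.eye(2),
            w=np.array([1.0, 0]), c=-0.5, feature_names=("a", "b"), ridge=0.0,
        )
        assert lda.decision_score(m2, np.array([0.5, 0.0])) == pytest.approx(0.0)
        assert lda.decision_score(m2, np.array([1.0, 0.0])) > 0
        assert lda.decision_score(m2, np.array([0.0, 0.0])) < 0

    def test_w_matches_linear_solver_oracle(self, rng):
        cov = np.array([[1.0, 0.3, 0.1], [0.3, 2.0, -0.2], [0.1, -0.2, 0.5]])
        X, y = gaussian_data(rng, [0, 0, 0], [1, 0.5, -0.3], cov, 300, 300)
        m = lda.fit_lda(X, y, ridge_scale=0.0)
        # independent oracle: Gaussian elimination with partial pivoting
        A = m.sigma.copy()
        b = (m.mu1 - m.mu0).copy()
        n = len(b)
        for col in range(n):
            p = col + np.argmax(np.abs(A[col:, col]))
            A[[col, p]] = A[[p, col]]
            b[[col, p]] = b[[p, col]]
            for r in range(col + 1, n):
                f = A[r, col] / A[col, col]
                A[r] -= f * A[col]
                b[r] -= f * b[col]
        w = np.zeros(n)
        for r in range(n - 1, -1, -1):
            w[r] = (b[r] - A[r, r + 1 :] @ w[r + 1 :]) / A[r, r]
        np.testing.assert_allclose(m.w, w, atol=1e-10)

    def test_duplicated_feature_handled_by_ridge(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.5], np.eye(1), 200, 200)
        X2 = np.hstack([X, X])  # exactly collinear
        m1 = lda.fit_lda(X, y)
        m2 = lda.fit_lda(X2, y)
        s1 = lda.decision_score(m1, X)
        s2 = lda.decision_score(m2, X2)
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_one_class_absent_rejected(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ValueError):
            lda.fit_lda(X, np.array(["shadow"] * 10))


class TestDecisionScore:
    def test_midpoint_scores_zero(self, rng):
        cov = np.array([[1.0, 0.2], [0.2, 0.8]])
        X, y = gaussian_data(rng, [0, 0], [2, 1], cov, 400, 400)
        m = lda.fit_lda(X, y)
        assert lda.decision_score(m, (m.mu0 + m.mu1) / 2) == pytest.approx(0.0, abs=1e-10)
        assert lda.decision_score(m, m.mu0) * lda.decision_score(m, m.mu1) < 0

    def test_score_equals_gaussian_log_density_ratio(self, rng):
        # the linear score must equal the brute-force two-Gaussian
        # log-density ratio with shared covariance, everywhere
        cov = np.array([[1.0, 0.4, 0.0], [0.4, 1.5, -0.3], [0.0, -0.3, 0.7]])
        X, y = gaussian_data(rng, [0, 0, 0], [1, -0.5, 0.25], cov, 250, 250)
        m = lda.fit_lda(X, y)
        pts = rng.normal(0, 2, size=(100, 3))
        scores = lda.decision_score(m, pts)
        oracle = multivariate_normal(m.mu1, m.sigma).logpdf(pts) - multivariate_normal(
            m.mu0, m.sigma
        ).logpdf(pts)
        np.testing.assert_allclose(scores, oracle, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = gaussian_data(rng, [0, 0], [1, 1], np.eye(2), 50, 50)
        m = lda.fit_lda(X, y)
        with pytest.raises(ValueError):
            lda.decision_score(m, np.zeros(3))


class TestInvariances:
    def test_affine_feature_rescaling_leaves_predictions_unchanged(self, rng):
        cov = np.array([[1.0, 0.3], [0.3, 0.5]])
        X, y = gaussian_data(rng, [0, 0], [1.2, 0.4], cov, 150, 150)
        m1 = lda.fit_lda(X, y, ridge_scale=0.0)
        scale = np.array([10.0, 0.01])
        m2 = lda.fit_lda(X * scale, y, ridge_scale=0.0)
        np.testing.assert_array_equal(lda.predict(m1, X), lda.predict(m2, X * scale))

    def test_label_swap_negates_scores(self, rng):
        X, y = gaussian_data(rng, [0, 0], [1, 1], np.eye(2), 120, 120)
        m = lda.fit_lda(X, y, ridge_scale=0.0)
        y_swapped = np.where(y == "shadow", "other", "shadow")
        m_sw = lda.fit_lda(X, y_swapped, ridge_scale=0.0)
        np.testing.assert_allclose(
            lda.decision_score(m_sw, X), -lda.decision_score(m, X), atol=1e-9
        )
        cm = lda.evaluate(m, X, y)
        cm_sw = lda.evaluate(m_sw, X, y_swapped)
        assert abs(cm_sw.dprime) == pytest.approx(abs(cm.dprime), abs=1e-9)

    def test_parameter_recovery_at_large_n(self, rng):
        # w-hat converges to Sigma^-1 (mu1 - mu0): < 5% relative error at n = 1e5
        cov = np.array([[1.0, 0.5, 0.2], [0.5, 1.2, -0.1], [0.2, -0.1, 0.8]])
        mu0, mu1 = np.zeros(3), np.array([0.8, -0.4, 0.3])
        X, y = gaussian_data(rng, mu0, mu1, cov, 100_000, 100_000)
        m = lda.fit_lda(X, y)
        w_true = np.linalg.solve(cov, mu1 - mu0)
        assert np.linalg.norm(m.w - w_true) / np.linalg.norm(w_true) < 0.05

    def test_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        cov = np.array([[1.0, 0.3], [0.3, 0.9]])
        X, y = gaussian_data(rng, [0, 0], [1, 0.5], cov, 200, 200)
        m = lda.fit_lda(X, y, ridge_scale=0.0)
        ref = sklearn.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        ours = lda.predict(m, X)
        assert np.mean(ours == ref.predict(X)) > 0.99


class TestEvaluate:
    def test_perfect_separation_hits_correction_ceiling(self):
        from scipy.stats import norm

        X = np.concatenate([np.zeros(50), np.ones(50)])[:, None]
        y = np.array(["shadow"] * 50 + ["other"] * 50)
        cm = lda.evaluate(None, X, y)
        assert cm.correction_applied
        assert cm.pH == pytest.approx(50.5 / 51)
        assert cm.pFA == pytest.approx(0.5 / 51)
        assert cm.dprime == pytest.approx(norm.ppf(50.5 / 51) - norm.ppf(0.5 / 51))

    def test_shuffled_labels_give_chance_dprime(self, rng):
        X = rng.normal(size=(4000, 2))
        y = np.where(rng.random(4000) < 0.5, "shadow", "other")
        cm = lda.evaluate(None, X, y)
        assert abs(cm.dprime) < 0.1

    def test_closed_form_dprime_recovery(self, rng):
        # 1-D classes N(0,1) vs N(1.5,1): optimal-criterion d' = 1.5
        X, y = gaussian_data(rng, [0.0], [1.5], np.eye(1), 20000, 20000)
        cm = lda.evaluate(None, X, y)
        assert cm.dprime == pytest.approx(1.5, abs=0.1)

    def test_kfold_close_to_resub_at_large_n(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.5], np.eye(1), 2000, 2000)
        cm_res = lda.evaluate(None, X, y, protocol="resub")
        cm_cv = lda.evaluate(None, X, y, protocol="kfold", seed=0)
        assert cm_cv.dprime == pytest.approx(cm_res.dprime, abs=0.15)

    def test_confusion_counts_sum_to_class_totals(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.0], np.eye(1), 80, 120)
        cm = lda.evaluate(None, X, y)
        assert cm.counts[0].sum() == 80
        assert cm.counts[1].sum() == 120


class TestRanking:
    def test_single_feature_is_rank_one(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.0], np.eye(1), 100, 100)
        r = lda.rank_features(X, y, ["only"])
        assert list(r["feature"]) == ["only"]
        assert list(r["rank"]) == [1]

    def test_noise_feature_ranked_last(self, rng):
        X, y = gaussian_data(rng, [0.0, 0.0], [2.0, 1.0], np.eye(2), 300, 300)
        X = np.hstack([X, rng.normal(size=(600, 1))])
        r = lda.rank_features(X, y, ["strong", "weak", "noise"])
        assert r.iloc[-1]["feature"] == "noise"
        assert abs(r.iloc[-1]["dprime"]) < 0.3


class TestIncrementalCurves:
    def test_none_variant_at_m4_matches_direct_evaluation(self, rng):
        cov = np.eye(4) + 0.2
        X, y = gaussian_data(rng, np.zeros(4), [1, 0.7, 0.4, 0.1], cov, 150, 150)
        names = ["C_Lum", "m_Lum", "sigma_Lum", "rho_Lum"]
        curves = lda.incremental_curves(X, y, names, luminance_features=names, n_boot=10)
        top = curves[(curves["n_properties"] == 4) & (curves["variant"] == "none")]
        cm = lda.evaluate(None, X, y)
        assert top["dprime"].iloc[0] == pytest.approx(cm.dprime, abs=1e-9)

    def test_nested_models_monotone(self, rng):
        # the fitted Mahalanobis separation is exactly monotone in nested
        # feature sets; the count-based confusion d' tracks it up to the
        # granularity of individual samples flipping sides
        cov = np.eye(4) + 0.1
        X, y = gaussian_data(rng, np.zeros(4), [1.0, 0.6, 0.3, 0.1], cov, 200, 200)
        names = ["a", "b", "c", "d"]
        prev_sep = 0.0
        for m in range(1, 5):
            model = lda.fit_lda(X[:, :m], y, ridge_scale=0.0)
            sep = float(np.sqrt((model.mu1 - model.mu0) @ model.w))
            assert sep >= prev_sep - 1e-9
            prev_sep = sep
        curves = lda.incremental_curves(X, y, names, luminance_features=names, n_boot=5)
        none = curves[curves["variant"] == "none"].sort_values("n_properties")
        diffs = np.diff(none["dprime"].to_numpy())
        assert np.all(diffs >= -0.2)  # count granularity at n = 200/class


class TestParametricBootstrap:
    def test_single_replicate_degenerate_interval(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.0], np.eye(1), 60, 60)
        ci = lda.parametric_bootstrap(X, y, n_boot=1, seed=5)
        assert ci.lo == ci.hi == ci.replicates[0]

    def test_deterministic_given_seed(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.2], np.eye(1), 80, 80)
        a = lda.parametric_bootstrap(X, y, n_boot=50, seed=42)
        b = lda.parametric_bootstrap(X, y, n_boot=50, seed=42)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_interval_brackets_point_for_gaussian_data(self, rng):
        X, y = gaussian_data(rng, [0.0], [1.5], np.eye(1), 400, 400)
        ci = lda.parametric_bootstrap(X, y, n_boot=300, seed=7)
        assert ci.lo < ci.point_dprime + 0.1
        assert ci.hi > ci.point_dprime - 0.1
        assert 0 < ci.hi - ci.lo < 1.0  # plausible width at n = 400/class
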