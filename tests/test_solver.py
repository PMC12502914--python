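import numpy as np
import pytest
from scipy.special import expit

from sparselink import (
    Family,
    PenaltyFactorVector,
    SolverConfig,
    deviance,
    fit_elastic_net,
    fit_sign_split_lasso,
    make_lambda_path,
    predict_response,
)
from sparselink.solver import DegeneratePathWarning, cv_tune_lambda1

from _oracle import elastic_net_objective, solve_elastic_net


def standardised(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


class TestLambdaPath:
    def test_lambda_max_analytic(self, rng):
        """lambda_max equals max_j |x_j . (y - ybar)| / (n * mixing)."""
        n, p = 50, 8
        X = standardised(rng, n, p)
        y = rng.standard_normal(n) + X[:, 2]
        mixing = 0.95
        path = make_lambda_path(X, y, Family.gaussian, mixing)
        expected = np.abs(X.T @ (y - y.mean())).max() / (n * mixing)
        assert path.values[0] == pytest.approx(expected, rel=1e-12)
        # just above lambda_max every penalised coefficient is zero
        fit = fit_elastic_net(X, y, Family.gaussian, mixing, path.values[0] * 1.001)
        assert np.all(fit.slopes == 0)

    def test_path_shape_and_monotonicity(self, rng):
        X = standardised(rng, 30, 5)
        y = rng.standard_normal(30)
        path = make_lambda_path(X, y, Family.gaussian, 1.0, n_values=60)
        assert len(path) == 60
        assert np.all(np.diff(path.values) < 0)
        assert path.values[-1] == pytest.approx(path.values[0] * 1e-4)

    def test_penalty_factor_scale_invariance(self, rng):
        """Doubling every finite factor is undone by the mean-1 rescale."""
        X = standardised(rng, 30, 4)
        y = rng.standard_normal(30) + X[:, 0]
        raw = np.array([0.5, 2.0, np.inf, 1.0, 1.5, np.inf, 3.0, 0.2])
        z1 = PenaltyFactorVector.from_raw(raw)
        z2 = PenaltyFactorVector.from_raw(2 * raw)
        p1 = make_lambda_path(X, y, Family.gaussian, 1.0, z1)
        p2 = make_lambda_path(X, y, Family.gaussian, 1.0, z2)
        np.testing.assert_allclose(p1.values, p2.values)

    def test_constant_target_degenerates_with_warning(self, rng):
        X = standardised(rng, 20, 3)
        with pytest.warns(DegeneratePathWarning):
            path = make_lambda_path(X, np.ones(20), Family.gaussian, 1.0)
        assert len(path) == 1


class TestElasticNet:
    def test_huge_lambda_gives_intercept_only(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40) + 2.0
        fit = fit_elastic_net(X, y, Family.gaussian, 0.95, 1e6)
        assert np.all(fit.slopes == 0)
        assert fit.intercept == pytest.approx(y.mean())
        yb = (rng.random(40) < 0.3).astype(float)
        fitb = fit_elastic_net(X, yb, Family.binomial, 0.95, 1e6)
        assert np.all(fitb.slopes == 0)
        assert expit(fitb.intercept) == pytest.approx(yb.mean(), abs=1e-6)

    def test_orthonormal_soft_thresholding(self, rng):
        """With X'X = nI the lasso solution is the soft-thresholded
        univariate covariance."""
        n, p = 64, 6
        M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)  # orthonormal columns, zero mean
        beta = np.array([1.0, -0.5, 0.0, 0.25, 0.0, 2.0])
        y = X @ beta + 0.1 * rng.standard_normal(n)
        lam = 0.3
        cfg = SolverConfig(standardise=False, tolerance=1e-12)
        fit = fit_elastic_net(X, y, Family.gaussian, 1.0, lam, cfg)
        cov = X.T @ (y - y.mean()) / n
        expected = np.sign(cov) * np.maximum(np.abs(cov) - lam, 0)
        np.testing.assert_allclose(fit.slopes, expected, atol=1e-7)

    @pytest.mark.parametrize("family", [Family.gaussian, Family.binomial])
    def test_matches_convex_oracle(self, rng, family, tight_config):
        n, p = 30, 8
        X = standardised(rng, n, p)
        eta = X @ (rng.standard_normal(p) * (rng.random(p) < 0.6))
        y = (
            eta + rng.standard_normal(n)
            if family is Family.gaussian
            else (rng.random(n) < expit(eta)).astype(float)
        )
        lam, mixing = 0.07, 0.95
        fit = fit_elastic_net(X, y, family, mixing, lam, tight_config)
        b0o, bo, fo = solve_elastic_net(X, y, family.value, lam, mixing)
        fm = elastic_net_objective(X, y, family.value, lam, mixing,
                                   fit.intercept, fit.slopes)
        assert fm == pytest.approx(fo, rel=1e-6, abs=1e-10)
        np.testing.assert_allclose(fit.slopes, bo, atol=1e-4)


class TestSignSplit:
    def test_full_shrinkage(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        z = PenaltyFactorVector.uniform(8)
        fit = fit_sign_split_lasso(X, y, Family.gaussian, 1e5, z)
        assert np.all(fit.gamma == 0)

    def test_uniform_factors_recover_standard_lasso(self, rng, tight_config):
        X = rng.standard_normal((40, 7)) * rng.uniform(0.5, 2.0, size=7)
        y = rng.standard_normal(40) + X[:, 0] - 0.5 * X[:, 3]
        lam = 0.05
        z = PenaltyFactorVector.uniform(14)
        ss = fit_sign_split_lasso(X, y, Family.gaussian, lam, z, tight_config)
        en = fit_elastic_net(X, y, Family.gaussian, 1.0, lam, tight_config)
        np.testing.assert_allclose(ss.slopes, en.slopes, atol=1e-7)
        assert ss.intercept == pytest.approx(en.intercept, abs=1e-7)

    def test_excluded_coordinates_stay_zero(self, rng, tight_config):
        n, p = 30, 5
        X = standardised(rng, n, p)
        y = rng.standard_normal(n) + 2 * X[:, 1]
        raw = np.ones(2 * p)
        raw[[0, 6, 9]] = np.inf
        z = PenaltyFactorVector.from_raw(raw)
        fit = fit_sign_split_lasso(X, y, Family.gaussian, 0.01, z, tight_config)
        assert np.all(fit.gamma[[0, 6, 9]] == 0)

    def test_kkt_stationarity(self, rng, tight_config):
        """Active coordinates satisfy grad + lam*z = 0; inactive ones
        grad + lam*z >= 0 (within tolerance)."""
        n, p = 40, 6
        X = standardised(rng, n, p)
        y = rng.standard_normal(n) + X[:, 0] - X[:, 4]
        z = PenaltyFactorVector.from_raw(np.exp(rng.normal(size=2 * p)))
        lam = 0.04
        fit = fit_sign_split_lasso(X, y, Family.gaussian, lam, z, tight_config)
        resid = y - fit.intercept - X @ fit.slopes
        g = np.concatenate([-X.T @ resid, X.T @ resid]) / n
        kkt = g + lam * z.values
        tol = 1e-6
        assert np.all(kkt[fit.gamma > 0] <= tol) and np.all(
            kkt[fit.gamma > 0] >= -tol
        )
        assert np.all(kkt[fit.gamma == 0] >= -tol)

    def test_sign_exclusivity(self, rng, tight_config):
        for trial in range(5):
            n, p = 35, 6
            X = standardised(rng, n, p)
            y = rng.standard_normal(n) + X @ rng.standard_normal(p)
            z = PenaltyFactorVector.from_raw(np.exp(rng.normal(size=2 * p)))
            fit = fit_sign_split_lasso(X, y, Family.gaussian, 0.03, z, tight_config)
            assert np.minimum(fit.gamma[:p], fit.gamma[p:]).max() <= 1e-8


class TestPredictAndDeviance:
    def test_logistic_of_zero_is_half(self):
        X = np.zeros((5, 3))
        out = predict_response(0.0, np.zeros(3), X, Family.binomial, "response")
        np.testing.assert_allclose(out, 0.5)

    def test_gaussian_link_equals_response(self, rng):
        X = rng.standard_normal((6, 2))
        s = rng.standard_normal(2)
        a = predict_response(0.3, s, X, Family.gaussian, "link")
        b = predict_response(0.3, s, X, Family.gaussian, "response")
        np.testing.assert_allclose(a, b)

    def test_logistic_monotone_and_bounded(self):
        X = np.linspace(-30, 30, 13)[:, None]
        out = predict_response(0.0, np.ones(1), X, Family.binomial, "response")
        assert np.all((out > 0) & (out < 1))
        assert np.all(np.diff(out) > 0)

    def test_deviance_closed_forms(self, rng):
        y = rng.standard_normal(10)
        assert deviance(y, y, Family.gaussian) == 0.0
        assert deviance(np.ones(4), np.full(4, 0.5), Family.binomial) == pytest.approx(
            -2 * np.log(0.5)
        )
        yhat = rng.random(10)
        perm = rng.permutation(10)
        assert deviance(y, yhat, Family.gaussian) == pytest.approx(
            deviance(y[perm], yhat[perm], Family.gaussian)
        )


class TestCvTuneLambda1:
    def test_pure_noise_selects_sparse_end(self, rng):
        n, p = 60, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        folds = (np.arange(n) % 5) + 1
        lam1 = cv_tune_lambda1(X, y, Family.gaussian, 0.95, folds)
        path = make_lambda_path(X, y, Family.gaussian, 0.95)
        # selected value in the sparser (upper) half of the path
        assert lam1 >= path.values[len(path) // 2]
        fit = fit_elastic_net(X, y, Family.gaussian, 0.95, lam1)
        assert np.count_nonzero(fit.slopes) <= p // 2

    def test_strong_signal_is_retained(self, rng):
        n, p = 60, 10
        X = rng.standard_normal((n, p))
        y = 3 * X[:, 4] + 0.2 * rng.standard_normal(n)
        folds = (np.arange(n) % 5) + 1
        lam1 = cv_tune_lambda1(X, y, Family.gaussian, 0.95, folds)
        fit = fit_elastic_net(X, y, Family.gaussian, 0.95, lam1)
        assert fit.slopes[4] != 0

    def test_deterministic(self, rng):
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        folds = (np.arange(n) % 4) + 1
        assert cv_tune_lambda1(X, y, Family.gaussian, 0.95, folds) == cv_tune_lambda1(
            X, y, Family.gaussian, 0.95, folds
        )
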