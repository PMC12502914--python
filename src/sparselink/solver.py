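"""Penalised GLM fitting engine.

Three layers:

* plain elastic-net fits and regularisation paths (stage 1), delegating the
  inner penalised least-squares solve to scikit-learn's coordinate-descent
  core, which minimises exactly ``1/(2n)·RSS + lam·(a·||b||_1 + (1-a)/2·||b||^2)``;
* a sign-split weighted non-negative lasso (stage 2): each slope is written
  as ``beta_j = gamma_j - gamma_{p+j}`` with ``gamma >= 0`` and the penalty
  ``lam · sum_j z_j · gamma_j`` applies a separate factor to each effect
  direction.  This is solved as a non-negative lasso on the column-augmented
  design ``[X | -X]`` with factor ``z_j`` absorbed by scaling column j by
  ``1/z_j``; a factor of +inf excludes the coordinate outright;
* binomial fits wrap either solve in iteratively reweighted least squares
  (IRLS) with working response and weights, probability-clamped at 1e-10.

Features are standardised internally (unit variance, means absorbed into the
unpenalised intercept); coefficients are returned on the original scale.
Penalty factors are rescaled so finite entries average one, which makes lam
comparable across factor choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .core import Family

PROB_CLAMP = 1e-10
#: minimum IRLS working weight, glmnet-style floor
WEIGHT_FLOOR = 1e-10


class SolverError(RuntimeError):
    """Raised on non-convergence; carries iteration diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegeneratePathWarning(UserWarning):
    """The null-model gradient vanishes; the lambda path collapses."""


@dataclass
class SolverConfig:
    """Numerical knobs for the coordinate-descent / IRLS solvers."""

    mixing: float = 0.95
    max_iterations: int = 100_000
    tolerance: float = 1e-7
    #: looser working tolerance for warm-started CV paths (scaled by the
    #: squared target norm inside the coordinate-descent core)
    path_tolerance: float = 1e-4
    #: per-chunk sweep budget for warm-started CV paths; bounds the work
    #: spent on the ill-conditioned near-interpolation tail
    path_max_iter: int = 2000
    standardise: bool = True
    max_irls: int = 200

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RegularisationPath:
    """Strictly decreasing positive lambda sequence, length <= 100."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PenaltyFactorVector:
    """Length-2p sign-specific penalty factors.

    Entries are strictly positive or +inf; +inf marks a coordinate that is
    excluded from the fit (hard exclusion, not a large finite number).
    Finite entries are rescaled to average exactly one.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values <= 0) or np.any(np.isnan(self.values)):
            raise ValueError("penalty factors must be in (0, +inf]")

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "PenaltyFactorVector":
        """Rescale raw factors so finite entries average one; keep +inf."""
        raw = np.asarray(raw, dtype=float).ravel()
        finite = np.isfinite(raw)
        values = raw.copy()
        if finite.any():
            values[finite] = raw[finite] / raw[finite].mean()
        return cls(values)

    @property
    def excluded(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @classmethod
    def uniform(cls, m: int) -> "PenaltyFactorVector":
        return cls(np.ones(m))


@dataclass
class GlmFit:
    """A single penalised GLM fit on the original feature scale."""

    intercept: float
    slopes: np.ndarray
    n_iter: int = 0
    gamma: np.ndarray | None = None  # sign-split fits only, length 2p


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _null_gradient(Xs: np.ndarray, y: np.ndarray, family: Family) -> np.ndarray:
    """Gradient of the mean log-likelihood at the intercept-only model,
    on the standardised feature scale."""
    n = y.shape[0]
    if family is Family.gaussian:
        resid = y - y.mean()
    else:
        pbar = np.clip(y.mean(), PROB_CLAMP, 1 - PROB_CLAMP)
        resid = y - pbar
    return Xs.T @ resid / n


def default_path_ratio(n: int, p: int) -> float:
    """lambda_min / lambda_max: 0.01 when p > n else 1e-4 (glmnet convention)."""
    return 0.01 if p > n else 1e-4


def _geometric_path(lam_max: float, ratio: float, n_values: int) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * ratio, n_values)


def make_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    mixing: float = 1.0,
    z: PenaltyFactorVector | None = None,
    n_values: int = 100,
    ratio: float | None = None,
) -> RegularisationPath:
    """Log-spaced decreasing lambda sequence from the smallest value that
    zeroes every penalised coefficient.

    With ``z`` of length 2p the path is for the sign-split problem on the
    augmented design ``[X | -X]`` (non-negative coordinates, so only
    positive-direction gradients can activate a coordinate); with ``z`` of
    length p or None it is for the plain (elastic-net) problem.
    """
    if mixing <= 0:
        raise ValueError("mixing must be positive to define a finite lambda max")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Xs, _, _ = _standardise(X)
    g = _null_gradient(Xs, y, family)
    if z is None:
        crit = np.abs(g)
        m = p
    elif z.values.size == 2 * p:
        signed = np.concatenate([g, -g])  # gradients of the augmented columns
        crit = np.where(z.excluded, -np.inf, np.maximum(signed, 0.0) / z.values)
        m = 2 * p
    elif z.values.size == p:
        crit = np.where(z.excluded, -np.inf, np.abs(g) / z.values)
        m = p
    else:
        raise ValueError("penalty factor length must be p or 2p")
    del m  # the augmented problem still has p effective features
    lam_max = float(np.max(crit)) / mixing
    if not np.isfinite(lam_max) or lam_max <= 0:
        warnings.warn(
            "null-model gradient vanishes; returning a degenerate single-value path",
            DegeneratePathWarning,
            stacklevel=2,
        )
        return RegularisationPath(np.array([1e-12]))
    if ratio is None:
        ratio = default_path_ratio(n, p)
    return RegularisationPath(_geometric_path(lam_max, ratio, n_values))


# ---------------------------------------------------------------------------
# gaussian path core with deviance-saturation early exit
# ---------------------------------------------------------------------------

#: stop a path once the training deviance ratio exceeds this (glmnet devmax)
DEV_SATURATION = 0.999
#: ... or once it gains less than this over a chunk of lambdas (glmnet fdev)
DEV_GAIN_EXIT = 1e-5
_PATH_CHUNK = 10


def _gaussian_path_coefs(
    A: np.ndarray,
    yc: np.ndarray,
    l1_ratio: float,
    lambdas: np.ndarray,
    positive: bool,
    config: SolverConfig,
) -> np.ndarray:
    """Warm-started coefficient path on centered data (columns x L).

    Fits lambdas in chunks and stops early once the fit saturates; the
    remaining positions repeat the last coefficients.  This mirrors the
    early-exit convention of coordinate-descent path solvers and avoids the
    near-interpolation regime at the smallest lambdas.
    """
    L = lambdas.size
    m = A.shape[1]
    coefs = np.zeros((m, L))
    null_dev = float(np.mean(yc**2))
    if null_dev == 0 or m == 0:
        return coefs
    Af = np.asfortranarray(A)
    warm = np.zeros(m)
    prev_ratio = 0.0
    done = 0
    while done < L:
        stop = min(done + _PATH_CHUNK, L)
        with warnings.catch_warnings():
            # path fits are working-accuracy by design; the sweep budget
            # below may leave the deepest lambdas short of full convergence
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, chunk, _ = enet_path(
                Af,
                yc,
                l1_ratio=l1_ratio,
                alphas=lambdas[done:stop],
                positive=positive,
                coef_init=warm.copy(),
                tol=config.path_tolerance,
                max_iter=config.path_max_iter,
                check_input=done == 0,
            )
        coefs[:, done:stop] = chunk
        warm = chunk[:, -1]
        done = stop
        resid = yc - Af @ warm
        ratio = 1.0 - float(np.mean(resid**2)) / null_dev
        if ratio > DEV_SATURATION or ratio - prev_ratio < DEV_GAIN_EXIT:
            coefs[:, done:] = warm[:, None]
            break
        prev_ratio = ratio
    return coefs


# ---------------------------------------------------------------------------
# weighted penalised least squares (the IRLS inner problem)
# ---------------------------------------------------------------------------

def _weighted_enet(
    est: ElasticNet,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
) -> tuple[float, np.ndarray]:
    """Minimise 1/(2n)·sum_i w_i (y_i - b0 - x_i·b)^2 + lam·penalty with an
    unpenalised intercept, via weighted centering + sqrt-weight row scaling.
    """
    sw = w.sum()
    xm = (w @ X) / sw
    ym = float(w @ y) / sw
    root = np.sqrt(w)[:, None]
    est.set_params(alpha=max(lam, 1e-300))
    est.fit((X - xm) * root, (y - ym) * np.sqrt(w))
    coef = est.coef_.copy()
    return ym - float(xm @ coef), coef


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    mixing: float,
    positive: bool,
    config: SolverConfig,
    coef_init: np.ndarray | None = None,
) -> tuple[float, np.ndarray, int]:
    """IRLS for binomial fits on a prepared (standardised/scaled) design."""
    n = y.shape[0]
    pbar = np.clip(y.mean(), PROB_CLAMP, 1 - PROB_CLAMP)
    b0 = float(np.log(pbar / (1 - pbar)))
    coef = np.zeros(X.shape[1]) if coef_init is None else coef_init.copy()
    est = ElasticNet(
        alpha=1.0,
        l1_ratio=mixing,
        fit_intercept=False,
        positive=positive,
        warm_start=True,
        max_iter=config.max_iterations,
        tol=min(config.tolerance, 1e-8),
    )
    tol = max(config.tolerance, 1e-10)
    for it in range(1, config.max_irls + 1):
        eta = b0 + X @ coef
        prob = np.clip(expit(eta), PROB_CLAMP, 1 - PROB_CLAMP)
        w = np.maximum(prob * (1 - prob), WEIGHT_FLOOR)
        work = eta + (y - prob) / w
        b0_new, coef_new = _weighted_enet(est, X, work, w, lam)
        delta = max(abs(b0_new - b0), float(np.max(np.abs(coef_new - coef), initial=0.0)))
        b0, coef = b0_new, coef_new
        if delta < tol:
            return b0, coef, it
    raise SolverError(
        "IRLS did not converge", iterations=config.max_irls, last_change=delta, lam=lam
    )


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def _strict(est_fit):
    """Run a scikit-learn fit with ConvergenceWarning promoted to SolverError."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            return est_fit()
        except ConvergenceWarning as exc:  # pragma: no cover - defensive
            raise SolverError("coordinate descent did not converge", detail=str(exc))


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    mixing: float = 0.95,
    lam: float = 1.0,
    config: SolverConfig | None = None,
) -> GlmFit:
    """Elastic-net penalised GLM fit at a single lambda.

    Minimises the family deviance/(2n) plus ``lam·(mixing·||b||_1 +
    (1-mixing)/2·||b||^2)`` over slopes, with an unpenalised intercept.
    """
    config = config or SolverConfig(mixing=mixing)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if config.standardise:
        Xs, mean, sd = _standardise(X)
    else:
        Xs, mean, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    if family is Family.gaussian:
        est = ElasticNet(
            alpha=max(lam, 1e-300),
            l1_ratio=mixing,
            fit_intercept=True,
            max_iter=config.max_iterations,
            tol=min(config.tolerance, 1e-8),
        )
        _strict(lambda: est.fit(Xs, y))
        b0, coef, n_iter = float(est.intercept_), est.coef_.copy(), int(est.n_iter_)
    else:
        b0, coef, n_iter = _irls(Xs, y, lam, mixing, False, config)
    slopes = coef / sd
    return GlmFit(intercept=b0 - float(slopes @ mean), slopes=slopes, n_iter=n_iter)


def _augmented_design(
    Xs: np.ndarray, z: PenaltyFactorVector
) -> tuple[np.ndarray, np.ndarray]:
    """Included-column augmented design [Xs | -Xs] with each column j scaled
    by 1/z_j; returns (design, included index array)."""
    p = Xs.shape[1]
    include = np.flatnonzero(~z.excluded)
    sign = np.where(include < p, 1.0, -1.0)
    cols = Xs[:, include % p] * (sign / z.values[include])
    return np.asfortranarray(cols), include


def fit_sign_split_lasso(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    lam: float,
    z: PenaltyFactorVector,
    config: SolverConfig | None = None,
) -> GlmFit:
    """Weighted non-negative lasso on the sign-split decomposition.

    Solves for gamma >= 0 (length 2p) minimising the family deviance/(2n) of
    the linear predictor ``b0 + X·(gamma[:p] - gamma[p:])`` plus
    ``lam · sum_j z_j·gamma_j``; coordinates with z_j = +inf are fixed at 0.
    """
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if z.values.size != 2 * p:
        raise ValueError("z must have 2p entries")
    if config.standardise:
        Xs, mean, sd = _standardise(X)
    else:
        Xs, mean, sd = X, np.zeros(p), np.ones(p)
    A, include = _augmented_design(Xs, z)
    if A.shape[1] == 0:
        b0 = (
            float(y.mean())
            if family is Family.gaussian
            else float(np.log(np.clip(y.mean(), PROB_CLAMP, 1 - PROB_CLAMP)
                              / np.clip(1 - y.mean(), PROB_CLAMP, 1 - PROB_CLAMP)))
        )
        return GlmFit(intercept=b0, slopes=np.zeros(p), gamma=np.zeros(2 * p))
    if family is Family.gaussian:
        est = ElasticNet(
            alpha=max(lam, 1e-300),
            l1_ratio=1.0,
            positive=True,
            fit_intercept=True,
            max_iter=config.max_iterations,
            tol=min(config.tolerance, 1e-8),
        )
        _strict(lambda: est.fit(A, y))
        b0, coef, n_iter = float(est.intercept_), est.coef_.copy(), int(est.n_iter_)
    else:
        b0, coef, n_iter = _irls(A, y, lam, 1.0, True, config)
    gamma_std = np.zeros(2 * p)
    gamma_std[include] = coef / z.values[include]
    gamma = gamma_std / np.concatenate([sd, sd])
    slopes_std = gamma_std[:p] - gamma_std[p:]
    slopes = slopes_std / sd
    return GlmFit(
        intercept=b0 - float(slopes @ mean), slopes=slopes, n_iter=n_iter, gamma=gamma
    )


def sign_split_path(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    z: PenaltyFactorVector,
    lambdas: np.ndarray,
    config: SolverConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-split lasso along a decreasing lambda sequence with warm starts.

    Returns (intercepts length L, gamma matrix 2p x L) on the original scale.
    """
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    lambdas = np.asarray(lambdas, dtype=float).ravel()
    p = X.shape[1]
    L = lambdas.size
    Xs, mean, sd = _standardise(X) if config.standardise else (
        X, np.zeros(p), np.ones(p))
    A, include = _augmented_design(Xs, z)
    intercepts = np.zeros(L)
    gammas = np.zeros((2 * p, L))
    if A.shape[1] == 0:
        if family is Family.gaussian:
            intercepts[:] = y.mean()
        else:
            pb = np.clip(y.mean(), PROB_CLAMP, 1 - PROB_CLAMP)
            intercepts[:] = np.log(pb / (1 - pb))
        return intercepts, gammas
    if family is Family.gaussian:
        ym = y.mean()
        Am = A.mean(axis=0)
        coefs = _gaussian_path_coefs(A - Am, y - ym, 1.0, lambdas, True, config)
        b0s = ym - Am @ coefs
    else:
        coefs = np.zeros((A.shape[1], L))
        b0s = np.zeros(L)
        warm = None
        for i, lam in enumerate(lambdas):
            b0s[i], coefs[:, i], _ = _irls(A, y, lam, 1.0, True, config, coef_init=warm)
            warm = coefs[:, i]
    gammas[include, :] = coefs / z.values[include, None]
    gammas /= np.concatenate([sd, sd])[:, None]
    intercepts[:] = b0s - mean @ (gammas[:p, :] - gammas[p:, :])
    return intercepts, gammas


def collapse_gamma(gamma: np.ndarray) -> np.ndarray:
    """Collapse a length-2p (or 2p x L) gamma into signed slopes."""
    m = gamma.shape[0] // 2
    return gamma[:m] - gamma[m:]


# ---------------------------------------------------------------------------
# prediction and loss
# ---------------------------------------------------------------------------

def predict_response(
    intercept: float,
    slopes: np.ndarray,
    X: np.ndarray,
    family: Family,
    type: str = "response",
) -> np.ndarray:
    """Linear predictor or its inverse-link transform."""
    eta = intercept + np.asarray(X, dtype=float) @ np.asarray(slopes, dtype=float)
    if type == "link":
        return eta
    return family.inverse_link(eta)


def deviance(y: np.ndarray, yhat: np.ndarray, family: Family) -> float:
    """Mean loss: squared error (gaussian) or binomial deviance, clamped."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if family is Family.gaussian:
        return float(np.mean((y - yhat) ** 2))
    prob = np.clip(yhat, PROB_CLAMP, 1 - PROB_CLAMP)
    return float(np.mean(-2 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))))


# ---------------------------------------------------------------------------
# stage-1 cross-validation
# ---------------------------------------------------------------------------

def elastic_net_predictions_by_path(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    family: Family,
    mixing: float,
    lambdas: np.ndarray,
    config: SolverConfig | None = None,
) -> np.ndarray:
    """Response-scale predictions on X_test for every lambda (n_test x L)."""
    config = config or SolverConfig(mixing=mixing)
    Xs, mean, sd = _standardise(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    lambdas = np.asarray(lambdas, dtype=float).ravel()
    if family is Family.gaussian:
        ym = y_train.mean()
        coefs = _gaussian_path_coefs(Xs, y_train - ym, mixing, lambdas, False, config)
        b0s = np.full(lambdas.size, ym)
    else:
        coefs = np.zeros((X_train.shape[1], lambdas.size))
        b0s = np.zeros(lambdas.size)
        warm = None
        for i, lam in enumerate(lambdas):
            b0s[i], coefs[:, i], _ = _irls(Xs, y_train, lam, mixing, False, config,
                                           coef_init=warm)
            warm = coefs[:, i]
    Xt = (np.asarray(X_test, dtype=float) - mean) / sd
    eta = b0s[None, :] + Xt @ coefs
    return family.inverse_link(eta)


def cv_tune_lambda1(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    mixing: float,
    fold_vector: np.ndarray,
    n_values: int = 100,
    config: SolverConfig | None = None,
) -> float:
    """Cross-validated lambda for the stage-1 elastic net.

    The path is built on the full data; each fold refits the whole path on
    the remaining samples; held-out predictions are pooled and the path value
    minimising the pooled deviance (MSE for gaussian) is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    fold_vector = np.asarray(fold_vector)
    path = make_lambda_path(X, y, family, mixing, n_values=n_values)
    lambdas = path.values
    oof = np.empty((y.shape[0], lambdas.size))
    for f in np.unique(fold_vector):
        test = fold_vector == f
        oof[test] = elastic_net_predictions_by_path(
            X[~test], y[~test], X[test], family, mixing, lambdas, config
        )
    losses = [deviance(y, oof[:, i], family) for i in range(lambdas.size)]
    return float(lambdas[int(np.argmin(losses))])
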