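"""Independent brute-force convex solvers used as references in tests.

Both penalised problems are rewritten with nonnegative variables so the
objective is smooth on a box (the L1 term becomes linear), and solved with
L-BFGS-B at tight tolerances.  These solvers share no code with the package
beyond numpy/scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def _loss_grad(eta: np.ndarray, y: np.ndarray, family: str):
    n = y.shape[0]
    if family == "gaussian":
        return float(np.sum((y - eta) ** 2) / (2 * n)), (eta - y) / n
    return (
        float(np.mean(np.logaddexp(0.0, eta) - y * eta)),
        (expit(eta) - y) / n,
    )


def solve_elastic_net(
    X: np.ndarray, y: np.ndarray, family: str, lam: float, mixing: float
) -> tuple[float, np.ndarray, float]:
    """Minimise loss/(2n or n) + lam*(mixing*||b||_1 + (1-mixing)/2*||b||^2)
    with free intercept, via the positive/negative split.

    Returns (intercept, slopes, objective).
    """
    n, p = X.shape

    def fg(u):
        b0, up, un = u[0], u[1 : 1 + p], u[1 + p :]
        beta = up - un
        loss, ge = _loss_grad(b0 + X @ beta, y, family)
        val = loss + lam * (
            mixing * np.sum(up + un) + 0.5 * (1 - mixing) * float(beta @ beta)
        )
        gx = X.T @ ge
        ridge = lam * (1 - mixing) * beta
        grad = np.concatenate(
            [[ge.sum()], gx + lam * mixing + ridge, -gx + lam * mixing - ridge]
        )
        return val, grad

    res = minimize(
        fg,
        np.zeros(1 + 2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0.0, None)] * (2 * p),
        options=dict(maxiter=100_000, maxfun=500_000, ftol=1e-16, gtol=1e-12),
    )
    return float(res.x[0]), res.x[1 : 1 + p] - res.x[1 + p :], float(res.fun)


def solve_sign_split(
    X: np.ndarray, y: np.ndarray, family: str, lam: float, z: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Minimise loss + lam*sum_j z_j*gamma_j over gamma >= 0 (length 2p);
    coordinates with z_j = +inf are pinned at zero.

    Returns (intercept, gamma, objective).
    """
    n, p = X.shape
    z = np.asarray(z, dtype=float)
    finite = np.isfinite(z)

    def fg(u):
        b0, g = u[0], u[1:]
        loss, ge = _loss_grad(b0 + X @ (g[:p] - g[p:]), y, family)
        val = loss + lam * float(np.sum(z[finite] * g[finite]))
        gx = X.T @ ge
        grad = np.concatenate([[ge.sum()], gx, -gx])
        grad[1:][finite] += lam * z[finite]
        return val, grad

    bounds = [(None, None)] + [
        (0.0, None if finite[j] else 0.0) for j in range(2 * p)
    ]
    res = minimize(
        fg,
        np.zeros(1 + 2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options=dict(maxiter=100_000, maxfun=500_000, ftol=1e-16, gtol=1e-12),
    )
    return float(res.x[0]), res.x[1:], float(res.fun)


def sign_split_objective(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    lam: float,
    z: np.ndarray,
    intercept: float,
    gamma: np.ndarray,
) -> float:
    p = X.shape[1]
    loss, _ = _loss_grad(intercept + X @ (gamma[:p] - gamma[p:]), y, family)
    finite = np.isfinite(z)
    return loss + lam * float(np.sum(z[finite] * gamma[finite]))


def elastic_net_objective(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    lam: float,
    mixing: float,
    intercept: float,
    slopes: np.ndarray,
) -> float:
    loss, _ = _loss_grad(intercept + X @ slopes, y, family)
    return loss + lam * (
        mixing * float(np.abs(slopes).sum())
        + 0.5 * (1 - mixing) * float(slopes @ slopes)
    )
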