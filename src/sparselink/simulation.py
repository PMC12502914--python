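"""Synthetic data for the multi-task / transfer study conditions.

Features are mean-zero Gaussian with the AR(1) correlation structure
``corr(x_j, x_l) = rho^|j-l|`` (rho = 0.5 by default), generated by the
exact AR(1) recursion rather than a p x p Cholesky factor.  True effects
combine a shared spike-and-slab vector ``theta_j ~ Bern(pi_theta) x N(0,1)``
with problem-specific ``delta_{j,k} ~ Bern(pi_delta) x N(0,1)``, so column k
of the effect matrix is ``B[:, k] = theta + delta[:, k]``.  Gaussian targets
add unit-variance noise to the linear predictor ``X B``; in multi-task mode
the q targets share one feature matrix, in transfer mode each problem draws
its own.  A binomial extension (targets Bernoulli(logistic(X B))) is
provided for completeness; the benchmark study conditions are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Family, Mode, Problem, ProblemSet


@dataclass
class SimConfig:
    """Study-condition parameters.

    Benchmark defaults: q = 3 problems, p = 200 AR(1)
    features with rho = 0.5, n = 100 training samples per problem in
    multi-task mode or (50, 100, 200) in transfer mode, unit Gaussian noise.
    ``n_test`` defaults to a desk-scale 2000 hold-out; set it to 10000 for
    tighter Monte-Carlo error on hold-out metrics.
    """

    mode: Mode = Mode.multi_task
    q: int = 3
    p: int = 200
    n_train: int | tuple[int, ...] | None = None
    n_test: int | tuple[int, ...] = 2000
    rho: float | tuple[float, ...] = 0.5
    pi_theta: float = 0.05
    pi_delta: float = 0.025
    family: Family = Family.gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.family = Family(self.family)
        if self.n_train is None:
            self.n_train = 100 if self.mode is Mode.multi_task else (50, 100, 200)
        if not 0 <= self.pi_theta <= 1 or not 0 <= self.pi_delta <= 1:
            raise ValueError("effect probabilities must be in [0, 1]")
        for r in np.atleast_1d(self.rho):
            if not 0 <= r < 1:
                raise ValueError("rho must be in [0, 1)")

    def per_problem(self, value) -> list:
        vals = np.atleast_1d(value)
        if vals.size == 1:
            return [vals.item()] * self.q
        if vals.size != self.q:
            raise ValueError(f"expected a scalar or {self.q} values, got {vals.size}")
        return list(vals)


@dataclass
class SimReplicate:
    """One draw of the generative process, split into train and test sets."""

    train: ProblemSet
    test: ProblemSet
    true_effects: np.ndarray  # p x q


def simulate_effects(
    p: int, q: int, pi_theta: float, pi_delta: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike-and-slab effect matrix B = theta 1' + Delta (p x q)."""
    theta = (rng.random(p) < pi_theta) * rng.standard_normal(p)
    delta = (rng.random((p, q)) < pi_delta) * rng.standard_normal((p, q))
    return theta[:, None] + delta


def simulate_features(
    n: int, p: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """n x p Gaussian matrix with row-wise correlation rho^|j-l|.

    Uses the AR(1) recursion x_1 = e_1, x_j = rho x_{j-1} + sqrt(1-rho^2) e_j,
    which reproduces the target covariance exactly in O(np).
    """
    eps = rng.standard_normal((n, p))
    if rho == 0:
        return eps
    X = np.empty((n, p))
    X[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + scale * eps[:, j]
    return X


def _targets(
    X: np.ndarray, b: np.ndarray, family: Family, rng: np.random.Generator
) -> np.ndarray:
    eta = X @ b
    if family is Family.gaussian:
        return eta + rng.standard_normal(eta.shape[0])
    from scipy.special import expit

    return (rng.random(eta.shape[0]) < expit(eta)).astype(float)


def simulate_replicate(config: SimConfig) -> SimReplicate:
    """Draw one replicate: shared or per-problem features, effects, targets,
    split into disjoint train/test problem sets with common true effects."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    q, p = config.q, config.p
    B = simulate_effects(p, q, config.pi_theta, config.pi_delta, rng)
    n_train = config.per_problem(config.n_train)
    n_test = config.per_problem(config.n_test)
    rho = config.per_problem(config.rho)
    train_problems, test_problems = [], []
    if config.mode is Mode.multi_task:
        if len(set(n_train)) != 1 or len(set(n_test)) != 1:
            raise ValueError("multi_task mode uses one shared sample size")
        n, m = n_train[0], n_test[0]
        X = simulate_features(n + m, p, rho[0], rng)
        for k in range(q):
            y = _targets(X, B[:, k], config.family, rng)
            train_problems.append(
                Problem(X[:n], y[:n], id=f"task{k + 1}")
            )
            test_problems.append(Problem(X[n:], y[n:], id=f"task{k + 1}"))
    else:
        for k in range(q):
            n, m = n_train[k], n_test[k]
            X = simulate_features(n + m, p, rho[k], rng)
            y = _targets(X, B[:, k], config.family, rng)
            train_problems.append(Problem(X[:n], y[:n], id=f"dataset{k + 1}"))
            test_problems.append(Problem(X[n:], y[n:], id=f"dataset{k + 1}"))
    return SimReplicate(
        train=ProblemSet(config.mode, train_problems, config.family),
        test=ProblemSet(config.mode, test_problems, config.family),
        true_effects=B,
    )
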