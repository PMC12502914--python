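import numpy as np
import pytest

from sparselink import Family, Mode, Problem, ProblemSet, SolverConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tight_config():
    """Solver settings tight enough for oracle/equivalence comparisons."""
    return SolverConfig(tolerance=1e-10, path_tolerance=1e-9, path_max_iter=10**6)


def make_gaussian_set(
    rng, mode=Mode.multi_task, q=3, p=12, n=40, signal=1.0, sparsity=0.3
):
    """Small synthetic problem set with partially shared effects."""
    shared = (rng.random(p) < sparsity) * rng.standard_normal(p) * signal
    problems = []
    if mode is Mode.multi_task:
        X = rng.standard_normal((n, p))
        for k in range(q):
            beta = shared + 0.3 * (rng.random(p) < sparsity) * rng.standard_normal(p)
            y = X @ beta + rng.standard_normal(n)
            problems.append(Problem(X, y, id=f"t{k + 1}"))
    else:
        for k in range(q):
            X = rng.standard_normal((n, p))
            beta = shared + 0.3 * (rng.random(p) < sparsity) * rng.standard_normal(p)
            y = X @ beta + rng.standard_normal(n)
            problems.append(Problem(X, y, id=f"d{k + 1}"))
    return ProblemSet(mode, problems, Family.gaussian)


@pytest.fixture
def small_multitask(rng):
    return make_gaussian_set(rng)


@pytest.fixture
def small_transfer(rng):
    return make_gaussian_set(rng, mode=Mode.transfer)
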