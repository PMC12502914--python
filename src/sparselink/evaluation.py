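"""Evaluation metrics and the replicate-level study harness.

Predictive performance is hold-out mean squared error, reported both raw and
as a ratio against the method's own standard-lasso reduction (the same
machinery with both scaling exponents forced to zero, hence identical folds
and paths — the ratio isolates the effect of adaptive penalisation and
information sharing).  Selection performance is sparsity (number of nonzero
slopes) and sign precision (fraction of nonzero estimates whose sign matches
the true effect; undefined for an empty model and then excluded from means).
For binomial problems a rank-based ROC-AUC is available.

Replicate summaries average the per-problem values first, then replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import estimator
from .core import Family, ProblemSet
from .estimator import HyperparameterGrid, SparselinkModel
from .simulation import SimConfig, simulate_replicate


def test_mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared residual."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    return float(np.mean((y - yhat) ** 2))


def sparsity(slopes: np.ndarray) -> int:
    """Number of exactly nonzero coefficients."""
    return int(np.count_nonzero(np.asarray(slopes)))


def sign_precision(est: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of nonzero estimates whose sign matches the truth;
    NaN when no estimate is nonzero."""
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    nz = est != 0
    if not nz.any():
        return float("nan")
    return float(np.mean(np.sign(est[nz]) == np.sign(truth[nz])))


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative
    (Mann-Whitney formulation; ties count half)."""
    y = np.asarray(y, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class MetricsRecord:
    """Per-problem evaluation of a fitted model against its lasso reduction."""

    config: str
    replicate: int
    problem: str
    test_mse: float
    test_mse_lasso: float
    mse_ratio_vs_lasso: float
    nonzero_count: int
    nonzero_count_lasso: int
    sign_precision: float
    sign_precision_lasso: float
    auc: float = float("nan")


def evaluate_model(
    model: SparselinkModel,
    reduction: SparselinkModel,
    test: ProblemSet,
    true_effects: np.ndarray | None,
    config_id: str = "config",
    replicate: int = 0,
) -> list[MetricsRecord]:
    records = []
    for k, pr in enumerate(test.problems):
        yhat = estimator.predict(model, pr.features, k, "response")
        yhat0 = estimator.predict(reduction, pr.features, k, "response")
        mse = test_mse(pr.target, yhat)
        mse0 = test_mse(pr.target, yhat0)
        truth = true_effects[:, k] if true_effects is not None else None
        rec = MetricsRecord(
            config=config_id,
            replicate=replicate,
            problem=pr.id,
            test_mse=mse,
            test_mse_lasso=mse0,
            mse_ratio_vs_lasso=mse / mse0 if mse0 > 0 else float("nan"),
            nonzero_count=sparsity(model.fits[k].slopes),
            nonzero_count_lasso=sparsity(reduction.fits[k].slopes),
            sign_precision=(
                sign_precision(model.fits[k].slopes, truth)
                if truth is not None
                else float("nan")
            ),
            sign_precision_lasso=(
                sign_precision(reduction.fits[k].slopes, truth)
                if truth is not None
                else float("nan")
            ),
        )
        if test.family is Family.binomial:
            try:
                rec.auc = roc_auc(pr.target, yhat)
            except ValueError:
                pass
        records.append(rec)
    return records


REDUCTION_GRID = HyperparameterGrid(delta_candidates=(0.0,))


def run_study(
    configs: list[SimConfig],
    n_reps: int = 10,
    grid: HyperparameterGrid | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, fit, and evaluate the method against its lasso reduction.

    For each config and replicate the full-grid model and the delta = {0}
    reduction are fitted on identical data with identical folds.  Returns a
    tidy table (config, replicate, problem, metric, value) including a
    ``mean`` pseudo-problem row averaging the problems of each replicate
    (NaN-aware, so undefined sign precision does not bias the mean).
    """
    grid = grid or HyperparameterGrid()
    root = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for ci, config in enumerate(configs):
        config_id = (
            f"{config.mode.value}:pi_theta={config.pi_theta}"
            f":pi_delta={config.pi_delta}"
        )
        streams = root.spawn(len(configs))[ci].generate_state(2 * n_reps) >> 1
        for rep in range(n_reps):
            cfg = SimConfig(
                mode=config.mode, q=config.q, p=config.p,
                n_train=config.n_train, n_test=config.n_test, rho=config.rho,
                pi_theta=config.pi_theta, pi_delta=config.pi_delta,
                family=config.family, seed=int(streams[2 * rep]),
            )
            replicate = simulate_replicate(cfg)
            fit_seed = int(streams[2 * rep + 1])
            model = estimator.fit(replicate.train, grid, n_folds, seed=fit_seed)
            reduction = estimator.fit(
                replicate.train, REDUCTION_GRID, n_folds, seed=fit_seed
            )
            records = evaluate_model(
                model, reduction, replicate.test, replicate.true_effects,
                config_id, rep,
            )
            for rec in records:
                rows.extend(_tidy(rec))
            rows.extend(_tidy_mean(records))
    return pd.DataFrame(rows, columns=["config", "replicate", "problem", "metric", "value"])


_METRICS = (
    "test_mse",
    "test_mse_lasso",
    "mse_ratio_vs_lasso",
    "nonzero_count",
    "nonzero_count_lasso",
    "sign_precision",
    "sign_precision_lasso",
    "auc",
)


def _tidy(rec: MetricsRecord) -> list[dict]:
    return [
        {
            "config": rec.config,
            "replicate": rec.replicate,
            "problem": rec.problem,
            "metric": m,
            "value": float(getattr(rec, m)),
        }
        for m in _METRICS
    ]


def _tidy_mean(records: list[MetricsRecord]) -> list[dict]:
    out = []
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in records], dtype=float)
        with np.errstate(invalid="ignore"):
            mean = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        out.append(
            {
                "config": records[0].config,
                "replicate": records[0].replicate,
                "problem": "mean",
                "metric": m,
                "value": mean,
            }
        )
    return out
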