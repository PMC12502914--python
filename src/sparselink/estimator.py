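"""The two-stage estimator.

Stage 1 fits each problem separately with a lasso-like elastic net
(mixing 0.95), tuning its penalty ``lambda1`` by cross-validation.  The
stage-1 coefficients of the same problem (internal) and of the other
problems (external) are turned into sign-specific penalty factors, and
stage 2 refits each problem with a weighted non-negative lasso on the
sign-split decomposition.  The stage-2 penalty ``lambda2`` and the two
weight-scaling exponents ``(delta_int, delta_ext)`` are tuned per problem by
a grid search with internal cross-validation: ``delta = 0`` switches an
information source off, so the grid contains the standard lasso
(``delta_int = delta_ext = 0``) and the internal-only adaptive lasso
(``delta_ext = 0``) as special cases.

Cross-validation excludes a fold jointly for all problems in multi-task
mode (shared samples) but only for the problem under tuning in transfer
mode (disjoint samples), where the other problems' stage-1 fits keep their
full-data coefficients.  ``lambda1`` is tuned once on the full data and held
fixed inside the hyperparameter CV.  CV curves are indexed by path position;
the reported ``lambda2`` is the full-data path value at the selected
position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import (
    CoefficientMatrix,
    Family,
    FoldAssignment,
    Mode,
    ProblemSet,
    assign_folds,
    validate_problem_set,
)
from .solver import (
    DegeneratePathWarning,
    PenaltyFactorVector,
    SolverConfig,
    collapse_gamma,
    cv_tune_lambda1,
    deviance,
    fit_elastic_net,
    make_lambda_path,
    predict_response,
    sign_split_path,
)
from .weights import ScalingExponents, WeightSet, external_weights, internal_weights

DEFAULT_DELTAS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class HyperparameterGrid:
    """Candidate scaling exponents (used for both delta_int and delta_ext)
    and the regularisation-path length."""

    delta_candidates: tuple[float, ...] = DEFAULT_DELTAS
    n_lambda: int = 100
    #: override for the external exponent only (defaults to delta_candidates);
    #: (0.0,) restricts the model to the internal-only adaptive lasso
    delta_ext_candidates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        def check(cands):
            cands = tuple(float(c) for c in cands)
            if not cands:
                raise ValueError("delta candidates must be non-empty")
            if any(c < 0 for c in cands) or list(cands) != sorted(cands):
                raise ValueError("delta candidates must be nonnegative, ascending")
            return cands

        self.delta_candidates = check(self.delta_candidates)
        if self.delta_ext_candidates is not None:
            self.delta_ext_candidates = check(self.delta_ext_candidates)
        if not 1 <= self.n_lambda <= 100:
            raise ValueError("n_lambda must be in 1..100")

    @property
    def pairs(self) -> list[tuple[float, float]]:
        ext = (
            self.delta_ext_candidates
            if self.delta_ext_candidates is not None
            else self.delta_candidates
        )
        return list(product(self.delta_candidates, ext))


@dataclass
class ProblemFit:
    """Tuned hyperparameters and fitted coefficients for one problem."""

    problem_id: str
    lambda1: float
    lambda2: float
    delta_int: float
    delta_ext: float
    stage1_intercept: float
    stage1_slopes: np.ndarray
    intercept: float
    gamma: np.ndarray  # length 2p, nonnegative, original scale
    cv_lambda2: np.ndarray  # n_pairs x L full-data path values
    cv_metric: np.ndarray  # n_pairs x L pooled out-of-fold metric
    fitted_values: np.ndarray  # response-scale predictions on the training rows

    @property
    def slopes(self) -> np.ndarray:
        return collapse_gamma(self.gamma)


@dataclass
class SparselinkModel:
    """Fitted two-stage model for a set of related problems."""

    mode: Mode
    family: Family
    seed: int
    n_folds: int
    grid: HyperparameterGrid
    feature_names: list[str]
    problem_ids: list[str]
    folds: FoldAssignment
    fits: list[ProblemFit]
    #: per-problem out-of-fold prediction cubes (n_k x n_pairs x L), retained
    #: only when fit(..., keep_oof=True); not serialised
    oof_predictions: list[np.ndarray] | None = None

    @property
    def p(self) -> int:
        return len(self.feature_names)

    @property
    def q(self) -> int:
        return len(self.fits)

    def to_json(self, path: str) -> None:
        doc = {
            "mode": self.mode.value,
            "family": self.family.value,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "grid": {
                "delta_candidates": list(self.grid.delta_candidates),
                "n_lambda": self.grid.n_lambda,
                "delta_ext_candidates": (
                    None
                    if self.grid.delta_ext_candidates is None
                    else list(self.grid.delta_ext_candidates)
                ),
            },
            "feature_names": self.feature_names,
            "problem_ids": self.problem_ids,
            "folds": [a.tolist() for a in self.folds.assignments],
            "fits": [
                {
                    "problem_id": f.problem_id,
                    "lambda1": f.lambda1,
                    "lambda2": f.lambda2,
                    "delta_int": f.delta_int,
                    "delta_ext": f.delta_ext,
                    "stage1_intercept": f.stage1_intercept,
                    "stage1_slopes": f.stage1_slopes.tolist(),
                    "intercept": f.intercept,
                    "gamma": f.gamma.tolist(),
                    "cv_lambda2": f.cv_lambda2.tolist(),
                    "cv_metric": f.cv_metric.tolist(),
                    "fitted_values": f.fitted_values.tolist(),
                }
                for f in self.fits
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "SparselinkModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            mode=Mode(doc["mode"]),
            family=Family(doc["family"]),
            seed=doc["seed"],
            n_folds=doc["n_folds"],
            grid=HyperparameterGrid(
                tuple(doc["grid"]["delta_candidates"]),
                doc["grid"]["n_lambda"],
                (
                    None
                    if doc["grid"].get("delta_ext_candidates") is None
                    else tuple(doc["grid"]["delta_ext_candidates"])
                ),
            ),
            feature_names=doc["feature_names"],
            problem_ids=doc["problem_ids"],
            folds=FoldAssignment(
                [np.asarray(a) for a in doc["folds"]], doc["n_folds"]
            ),
            fits=[
                ProblemFit(
                    problem_id=f["problem_id"],
                    lambda1=f["lambda1"],
                    lambda2=f["lambda2"],
                    delta_int=f["delta_int"],
                    delta_ext=f["delta_ext"],
                    stage1_intercept=f["stage1_intercept"],
                    stage1_slopes=np.asarray(f["stage1_slopes"]),
                    intercept=f["intercept"],
                    gamma=np.asarray(f["gamma"]),
                    cv_lambda2=np.asarray(f["cv_lambda2"]),
                    cv_metric=np.asarray(f["cv_metric"]),
                    fitted_values=np.asarray(f["fitted_values"]),
                )
                for f in doc["fits"]
            ],
        )


def cv_metric(y: np.ndarray, out_of_fold_predictions: np.ndarray, family: Family) -> float:
    """Pooled out-of-fold loss: MSE (gaussian) or mean binomial deviance."""
    return deviance(y, out_of_fold_predictions, family)


def select_hyperparameters(
    table: dict[tuple[float, float, float], float],
) -> tuple[float, float, float]:
    """Argmin of a {(lambda2, delta_int, delta_ext): metric} table.

    Exact ties are broken toward less transfer, then less adaptation, then
    stronger shrinkage: delta_ext = 0 first, then delta_int = 0, then the
    larger lambda2.
    """
    if not table:
        raise ValueError("empty hyperparameter table")
    key = min(table, key=lambda k: (table[k], k[2], k[1], -k[0]))
    return key


def _stage2_lambdas(
    X: np.ndarray,
    y: np.ndarray,
    family: Family,
    z: PenaltyFactorVector,
    n_lambda: int,
) -> np.ndarray:
    """Sign-split path, padded to fixed length so positions always align."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneratePathWarning)
        path = make_lambda_path(X, y, family, 1.0, z, n_values=n_lambda)
    lam = path.values
    if lam.size < n_lambda:
        lam = np.full(n_lambda, lam[0])
    return lam


def _weights_for(B: np.ndarray, k: int) -> WeightSet:
    internal = internal_weights(B[:, k])
    external = external_weights(np.delete(B, k, axis=1))
    return WeightSet(internal=internal, external=external)


def fit(
    ps: ProblemSet,
    grid: HyperparameterGrid | None = None,
    n_folds: int = 10,
    seed: int = 0,
    config: SolverConfig | None = None,
    stratify: bool | None = None,
    ridge_refit: bool = False,
    keep_oof: bool = False,
) -> SparselinkModel:
    """Fit the two-stage model to a validated problem set.

    ``ridge_refit`` optionally replaces a problem's stage-1 fit with a
    cross-validated ridge fit when the lasso-like elastic net returns an
    all-zero slope vector (off by default).
    """
    ps = validate_problem_set(ps)
    grid = grid or HyperparameterGrid()
    config = config or SolverConfig()
    folds = assign_folds(ps, n_folds=n_folds, seed=seed, stratify=stratify)
    family = ps.family
    p, q = ps.p, ps.q
    L = grid.n_lambda
    pairs = grid.pairs
    n_pairs = len(pairs)

    # ---- stage 1: tune lambda1 once per problem, fit on full data -------
    lambda1 = np.empty(q)
    stage1 = []
    B_full = np.empty((p, q))
    for k, pr in enumerate(ps.problems):
        lambda1[k] = cv_tune_lambda1(
            pr.features, pr.target, family, config.mixing,
            folds.assignments[k], n_values=L, config=config,
        )
        fit_k = fit_elastic_net(
            pr.features, pr.target, family, config.mixing, lambda1[k], config
        )
        if ridge_refit and not np.any(fit_k.slopes):
            fit_k = _ridge_stage1(pr.features, pr.target, family,
                                  folds.assignments[k], L, config)
        stage1.append(fit_k)
        B_full[:, k] = fit_k.slopes

    # ---- hyperparameter cross-validation --------------------------------
    oof = [np.full((pr.n, n_pairs, L), np.nan) for pr in ps.problems]

    def run_fold(k: int, Bm: np.ndarray, train: np.ndarray, test: np.ndarray) -> None:
        pr = ps.problems[k]
        Xtr, ytr = pr.features[train], pr.target[train]
        Xte = pr.features[test]
        w = _weights_for(Bm, k)
        # distinct (delta_int, delta_ext) pairs often share one penalty-factor
        # vector (always when stage-1 slopes are all zero), so path fits are
        # memoised on the factor values
        cache: dict[bytes, np.ndarray] = {}
        for pi, (di, de) in enumerate(pairs):
            z = penalty_factors_for(w, di, de)
            key = z.values.tobytes()
            preds = cache.get(key)
            if preds is None:
                lambdas = _stage2_lambdas(Xtr, ytr, family, z, L)
                ints, gammas = sign_split_path(Xtr, ytr, family, z, lambdas, config)
                slopes = gammas[:p, :] - gammas[p:, :]
                eta = ints[None, :] + Xte @ slopes
                preds = cache[key] = family.inverse_link(eta)
            oof[k][test, pi, :] = preds

    if ps.mode is Mode.multi_task:
        for f in range(1, n_folds + 1):
            train = folds.train_indices(0, f)
            test = folds.test_indices(0, f)
            Bm = np.empty((p, q))
            for k, pr in enumerate(ps.problems):
                Bm[:, k] = fit_elastic_net(
                    pr.features[train], pr.target[train], family,
                    config.mixing, lambda1[k], config,
                ).slopes
            for k in range(q):
                run_fold(k, Bm, train, test)
    else:
        for k, pr in enumerate(ps.problems):
            for f in range(1, n_folds + 1):
                train = folds.train_indices(k, f)
                test = folds.test_indices(k, f)
                Bm = B_full.copy()
                Bm[:, k] = fit_elastic_net(
                    pr.features[train], pr.target[train], family,
                    config.mixing, lambda1[k], config,
                ).slopes
                run_fold(k, Bm, train, test)

    # ---- selection and final fits ---------------------------------------
    fits = []
    for k, pr in enumerate(ps.problems):
        w_full = _weights_for(B_full, k)
        cv_lam = np.empty((n_pairs, L))
        cv_met = np.empty((n_pairs, L))
        table: dict[tuple[float, float, float], float] = {}
        where: dict[tuple[float, float, float], tuple[int, int]] = {}
        for pi, (di, de) in enumerate(pairs):
            z = penalty_factors_for(w_full, di, de)
            cv_lam[pi] = _stage2_lambdas(pr.features, pr.target, family, z, L)
            for pos in range(L):
                m = cv_metric(pr.target, oof[k][:, pi, pos], family)
                cv_met[pi, pos] = m
                key = (float(cv_lam[pi, pos]), di, de)
                table[key] = m
                where[key] = (pi, pos)
        lam2, di, de = select_hyperparameters(table)
        pi, pos = where[(lam2, di, de)]
        z = penalty_factors_for(w_full, di, de)
        ints, gammas = sign_split_path(
            pr.features, pr.target, family, z, cv_lam[pi], config
        )
        gamma = gammas[:, pos]
        intercept = float(ints[pos])
        fitted = predict_response(
            intercept, collapse_gamma(gamma), pr.features, family, "response"
        )
        fits.append(
            ProblemFit(
                problem_id=pr.id,
                lambda1=float(lambda1[k]),
                lambda2=float(lam2),
                delta_int=float(di),
                delta_ext=float(de),
                stage1_intercept=float(stage1[k].intercept),
                stage1_slopes=stage1[k].slopes,
                intercept=intercept,
                gamma=gamma,
                cv_lambda2=cv_lam,
                cv_metric=cv_met,
                fitted_values=fitted,
            )
        )

    return SparselinkModel(
        mode=ps.mode,
        family=family,
        seed=seed,
        n_folds=n_folds,
        grid=grid,
        feature_names=ps.feature_names,
        problem_ids=ps.problem_ids,
        folds=folds,
        fits=fits,
        oof_predictions=oof if keep_oof else None,
    )


def penalty_factors_for(w: WeightSet, delta_int: float, delta_ext: float) -> PenaltyFactorVector:
    from .weights import penalty_factors

    return penalty_factors(w, ScalingExponents(delta_int, delta_ext))


def _ridge_stage1(X, y, family, fold_vector, n_lambda, config):
    """CV-tuned ridge fallback for an all-zero lasso-like stage-1 fit.

    The path is anchored at the lambda-max of a barely-L1 mixture (a pure
    ridge path has no finite all-zero point)."""
    ridge = SolverConfig(
        mixing=0.0,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        standardise=config.standardise,
    )
    lam = cv_tune_lambda1(X, y, family, 1e-3, fold_vector, n_lambda, ridge)
    return fit_elastic_net(X, y, family, 0.0, lam, ridge)


def predict(
    model: SparselinkModel,
    X_new,
    problem: int = 0,
    type: str = "response",
) -> np.ndarray:
    """Predictions from one problem's final coefficients.

    A DataFrame input is aligned to the model's feature names (order-free);
    a plain array must have the model's column count.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing!r}, unexpected {extra!r}"
            )
        X_new = X_new[model.feature_names].to_numpy(dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.p:
        raise ValueError(
            f"expected {model.p} feature columns, got {X_new.shape[1] if X_new.ndim == 2 else 'non-matrix'}"
        )
    f = model.fits[problem]
    return predict_response(f.intercept, f.slopes, X_new, model.family, type)


def coefficients(model: SparselinkModel) -> CoefficientMatrix:
    """Final intercepts and collapsed slopes as a (p+1) x q matrix."""
    return CoefficientMatrix(
        intercepts=np.array([f.intercept for f in model.fits]),
        slopes=np.column_stack([f.slopes for f in model.fits]),
    )
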