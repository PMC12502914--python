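"""Data model for collections of related regression problems.

A *problem* is one (features, target) pair. A :class:`ProblemSet` bundles q
related problems that share the same p features, either over the same samples
(multi-task learning: one feature matrix, several targets) or over disjoint
sample sets (transfer learning: one feature matrix and target per dataset).

This module also owns cross-validation fold assignment and the delimited-text
readers/writers used by the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Base class for problem-set validation failures."""


class DimensionMismatchError(ValidationError):
    """Feature dimensions differ across problems, or shapes are inconsistent."""


class MissingValueError(ValidationError):
    """Features or targets contain NaN/inf."""


class NonBinaryTargetError(ValidationError):
    """A binomial target contains values other than 0 and 1."""


class SharedMatrixError(ValidationError):
    """Multi-task problems do not share one identical feature matrix."""


class FoldSizeError(ValidationError):
    """A problem has fewer samples than the requested number of folds."""


class Family(str, Enum):
    """GLM family: identity link with squared-error loss, or logit link with
    binomial deviance."""

    gaussian = "gaussian"
    binomial = "binomial"

    @property
    def link(self) -> str:
        return "identity" if self is Family.gaussian else "logit"

    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        """Map a linear predictor to the response scale."""
        eta = np.asarray(eta, dtype=float)
        if self is Family.gaussian:
            return eta
        from scipy.special import expit

        return expit(eta)


class Mode(str, Enum):
    multi_task = "multi_task"
    transfer = "transfer"


@dataclass
class Problem:
    """One regression problem: an n_k x p feature matrix and a length-n_k target."""

    features: np.ndarray
    target: np.ndarray
    id: str = "problem"
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.target = np.asarray(self.target, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]


@dataclass
class ProblemSet:
    """q related problems with a common family and learning mode."""

    mode: Mode
    problems: list[Problem]
    family: Family

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.family = Family(self.family)

    @property
    def q(self) -> int:
        return len(self.problems)

    @property
    def p(self) -> int:
        return self.problems[0].p

    @property
    def feature_names(self) -> list[str]:
        names = self.problems[0].feature_names
        if names is None:
            names = [f"x{j + 1}" for j in range(self.p)]
        return names

    @property
    def problem_ids(self) -> list[str]:
        return [pr.id for pr in self.problems]


def validate_problem_set(ps: ProblemSet) -> ProblemSet:
    """Check the structural invariants of a problem set; return it unchanged.

    Raises a distinct :class:`ValidationError` subclass per failure mode.
    """
    if ps.q < 1:
        raise ValidationError("a problem set needs at least one problem")
    p = ps.problems[0].p
    for pr in ps.problems:
        if pr.features.ndim != 2:
            raise DimensionMismatchError(f"problem {pr.id!r}: features must be 2-D")
        if pr.p != p:
            raise DimensionMismatchError(
                f"problem {pr.id!r} has {pr.p} features, expected {p}"
            )
        if pr.target.shape[0] != pr.n:
            raise DimensionMismatchError(
                f"problem {pr.id!r}: target length {pr.target.shape[0]} "
                f"!= sample count {pr.n}"
            )
        if pr.n < 2:
            raise ValidationError(f"problem {pr.id!r}: needs at least 2 samples")
        if not np.isfinite(pr.features).all():
            raise MissingValueError(f"problem {pr.id!r}: non-finite feature values")
        if not np.isfinite(pr.target).all():
            raise MissingValueError(f"problem {pr.id!r}: non-finite target values")
        if ps.family is Family.binomial and not np.isin(pr.target, (0.0, 1.0)).all():
            raise NonBinaryTargetError(
                f"problem {pr.id!r}: binomial target must contain only 0 and 1"
            )
    if ps.mode is Mode.multi_task:
        ref = ps.problems[0]
        for pr in ps.problems[1:]:
            if pr.n != ref.n or not np.array_equal(pr.features, ref.features):
                raise SharedMatrixError(
                    "multi_task mode requires one identical feature matrix "
                    f"shared by all problems; problem {pr.id!r} differs"
                )
    return ps


@dataclass
class FoldAssignment:
    """Per-problem fold identifiers in 1..n_folds.

    In multi_task mode all problems carry one common assignment; in transfer
    mode assignments are drawn independently per problem.
    """

    assignments: list[np.ndarray]
    n_folds: int

    def train_indices(self, problem: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[problem] != fold)

    def test_indices(self, problem: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[problem] == fold)


def _balanced_labels(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    labels = (np.arange(n) % n_folds) + 1
    out = np.empty(n, dtype=int)
    out[rng.permutation(n)] = labels
    return out


def _stratified_labels(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    # one cyclic label stream threaded through the classes keeps both the
    # per-class and the global fold sizes balanced to within one sample
    n = y.shape[0]
    out = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        out[idx] = ((np.arange(idx.size) + offset) % n_folds) + 1
        offset += idx.size
    return out


def assign_folds(
    ps: ProblemSet,
    n_folds: int = 10,
    seed: int | np.random.SeedSequence = 0,
    stratify: bool | None = None,
) -> FoldAssignment:
    """Balanced random fold assignment, deterministic given the seed.

    Stratification (class proportions preserved per fold) defaults to on for
    the binomial family. Multi-task mode draws one common partition shared by
    all problems; with stratification it is stratified against the first
    problem's target, the only consistent choice for a shared partition.
    Per-problem random streams are spawned from the seed, so a problem's
    assignment in transfer mode depends only on the seed and its position.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if stratify is None:
        stratify = ps.family is Family.binomial
    for pr in ps.problems:
        if pr.n < n_folds:
            raise FoldSizeError(
                f"problem {pr.id!r}: {pr.n} samples < {n_folds} folds"
            )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(ps.q)
    if ps.mode is Mode.multi_task:
        rng = np.random.default_rng(children[0])
        y0 = ps.problems[0].target
        if stratify and ps.family is Family.binomial:
            labels = _stratified_labels(y0, n_folds, rng)
        else:
            labels = _balanced_labels(y0.shape[0], n_folds, rng)
        assignments = [labels.copy() for _ in range(ps.q)]
    else:
        assignments = []
        for pr, child in zip(ps.problems, children):
            rng = np.random.default_rng(child)
            if stratify and ps.family is Family.binomial:
                assignments.append(_stratified_labels(pr.target, n_folds, rng))
            else:
                assignments.append(_balanced_labels(pr.n, n_folds, rng))
    return FoldAssignment(assignments=assignments, n_folds=n_folds)


@dataclass
class CoefficientMatrix:
    """Fitted intercepts (length q) and slopes (p x q), one column per problem."""

    intercepts: np.ndarray
    slopes: np.ndarray

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float).ravel()
        self.slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))

    def to_frame(
        self,
        feature_names: Sequence[str] | None = None,
        problem_ids: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        p, q = self.slopes.shape
        feature_names = list(feature_names) if feature_names else [
            f"x{j + 1}" for j in range(p)
        ]
        problem_ids = list(problem_ids) if problem_ids else [
            f"problem{k + 1}" for k in range(q)
        ]
        data = np.vstack([self.intercepts, self.slopes])
        return pd.DataFrame(data, index=["(intercept)"] + feature_names,
                            columns=problem_ids)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_matrix(path: str) -> pd.DataFrame:
    """Read a samples x features table (header = feature names; an initial
    non-numeric column is taken as sample ids)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
        df.index.name = None
    if not all(pd.api.types.is_numeric_dtype(df[c]) for c in df.columns):
        raise MissingValueError(f"{path}: non-numeric feature columns")
    return df


def read_target_vector(path: str) -> pd.Series:
    """Read a one-column target table (optionally preceded by sample ids)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] > 1 and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
        df.index.name = None
    if df.shape[1] != 1:
        raise ValidationError(f"{path}: expected a single target column")
    return df.iloc[:, 0]


def write_coefficient_matrix(
    cm: CoefficientMatrix,
    path: str,
    feature_names: Sequence[str] | None = None,
    problem_ids: Sequence[str] | None = None,
) -> None:
    cm.to_frame(feature_names, problem_ids).to_csv(
        path, sep=_sep_for(path), index_label=""
    )


def read_coefficient_matrix(path: str) -> CoefficientMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return CoefficientMatrix(
        intercepts=df.iloc[0].to_numpy(), slopes=df.iloc[1:].to_numpy()
    )
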