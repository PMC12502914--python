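"""Sign-specific internal/external weights and derived penalty factors.

Stage-1 coefficients carry directional evidence: a positive initial estimate
supports a positive final effect and argues against a negative one.  Each
feature j in problem k therefore gets four nonnegative weights — internal
(from problem k itself) and external (summed over the other problems), each
split into a positive-direction slot (index j) and a negative-direction slot
(index p+j):

    internal:  w_int[j]   = max(0, beta_k[j])      w_int[p+j] = |min(0, beta_k[j])|
    external:  w_ext[j]   = sum_l max(0, beta_l[j])
               w_ext[p+j] = |sum_l min(0, beta_l[j])|      (l over other problems)

At most one internal slot per feature is nonzero; both external slots can be.
The prior weight of coordinate j is ``w_int[j]^d_int + w_ext[j]^d_ext`` with
the convention 0^0 = 1, so a zero exponent switches that information source
off entirely.  Penalty factors are the reciprocals of the prior weights
(+inf when the prior is zero, which excludes the coordinate), rescaled so
finite entries average one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import PenaltyFactorVector


@dataclass
class WeightSet:
    """Internal and external sign-specific weights (each length 2p) for one
    problem."""

    internal: np.ndarray
    external: np.ndarray

    def __post_init__(self) -> None:
        self.internal = np.asarray(self.internal, dtype=float).ravel()
        self.external = np.asarray(self.external, dtype=float).ravel()
        if self.internal.shape != self.external.shape:
            raise ValueError("internal and external weights must share a length")
        if np.any(self.internal < 0) or np.any(self.external < 0):
            raise ValueError("weights must be nonnegative")


@dataclass
class ScalingExponents:
    """Exponents applied to internal/external weights; 0 switches a source off."""

    delta_int: float = 0.0
    delta_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_int < 0 or self.delta_ext < 0:
            raise ValueError("scaling exponents must be nonnegative")


def internal_weights(beta_k: np.ndarray) -> np.ndarray:
    """Positive parts in slots 1..p, absolute negative parts in slots p+1..2p."""
    beta_k = np.asarray(beta_k, dtype=float).ravel()
    return np.concatenate(
        [np.maximum(0.0, beta_k), np.abs(np.minimum(0.0, beta_k))]
    )


def external_weights(B_other: np.ndarray) -> np.ndarray:
    """Per-feature sums of positive and of negative parts over the other
    problems' coefficient columns (p x (q-1)); all-zero when q = 1."""
    B_other = np.asarray(B_other, dtype=float)
    if B_other.ndim == 1:
        B_other = B_other[:, None]
    if B_other.shape[1] == 0:
        return np.zeros(2 * B_other.shape[0])
    pos = np.maximum(0.0, B_other).sum(axis=1)
    neg = np.abs(np.minimum(0.0, B_other).sum(axis=1))
    return np.concatenate([pos, neg])


def _power(base: np.ndarray, exponent: float) -> np.ndarray:
    # 0^0 := 1, applied per term: a switched-off source contributes 1
    if exponent == 0.0:
        return np.ones_like(base)
    return base ** exponent


def penalty_factors(w: WeightSet, d: ScalingExponents) -> PenaltyFactorVector:
    """Penalty factors 1 / (w_int^d_int + w_ext^d_ext), mean-1 rescaled.

    A zero prior weight maps to +inf (the coordinate direction is excluded
    from the stage-2 fit).
    """
    prior = _power(w.internal, d.delta_int) + _power(w.external, d.delta_ext)
    with np.errstate(divide="ignore"):
        raw = np.where(prior > 0, 1.0 / np.where(prior > 0, prior, 1.0), np.inf)
    return PenaltyFactorVector.from_raw(raw)
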