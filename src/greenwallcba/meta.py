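"""Fixed-effect inverse-variance pooling of transferred unit values.

Standard errors are imputed from whatever uncertainty statement a study
provides:

* interval (lo, hi) — treated as a 95% confidence interval of a normal
  estimate, so the relative SE is ``((hi - lo) / (2 * 1.96)) / midpoint``;
* reported SE — the relative SE on the original percentage scale carries
  over unchanged to the unit-value scale (every transfer step is linear);
* none — SE is assumed to be 50% of the point estimate.

Weights are ``W_g = 1 / SE_g²`` and the pooled mean is
``sum(W_g * Y_g) / sum(W_g)`` with pooled SE ``1 / sqrt(sum(W_g))`` — the
minimum-variance linear combination.  No between-study heterogeneity
component is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError, ZeroUncertaintyError
from .transfer import (
    IntervalUncertainty,
    NoUncertainty,
    ReportedRelativeSE,
    Uncertainty,
    UnitValueEstimate,
)

#: two-sided 95% normal quantile used to invert confidence intervals
Z_95 = 1.96

#: assumed relative SE when a study reports no uncertainty at all
DEFAULT_RELATIVE_SE = 0.5


@dataclass(frozen=True)
class WeightedEstimate:
    """One study's effect with its variance and inverse-variance weight."""

    study_id: str
    effect: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ZeroUncertaintyError(
                f"{self.study_id}: SE must be > 0, got {self.se}"
            )

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def weight(self) -> float:
        return 1.0 / self.variance


@dataclass(frozen=True)
class MetaResult:
    weighted_mean: float
    pooled_se: float
    relative_weights: dict[str, float]
    n_studies: int


def impute_se(uncertainty: Uncertainty, point_effect: float) -> float:
    """Standard error of ``point_effect`` implied by an uncertainty statement."""
    if not point_effect > 0:
        raise InvalidParameterError(
            f"point effect must be > 0 for SE imputation, got {point_effect}"
        )
    if isinstance(uncertainty, IntervalUncertainty):
        half_width = 0.5 * (uncertainty.hi_pct - uncertainty.lo_pct)
        relative_se = (half_width / Z_95) / uncertainty.midpoint_pct
    elif isinstance(uncertainty, ReportedRelativeSE):
        relative_se = uncertainty.relative_se
    elif isinstance(uncertainty, NoUncertainty):
        relative_se = DEFAULT_RELATIVE_SE
    else:  # pragma: no cover - exhaustive over the union
        raise TypeError(f"unknown uncertainty type: {type(uncertainty)!r}")
    if relative_se == 0:
        raise ZeroUncertaintyError("degenerate uncertainty implies an infinite weight")
    return relative_se * point_effect


def to_weighted(estimates: list[UnitValueEstimate]) -> list[WeightedEstimate]:
    """Impute SEs where needed and wrap estimates for pooling."""
    out = []
    for est in estimates:
        se = est.se if est.se is not None else impute_se(est.uncertainty, est.unit_value)
        out.append(WeightedEstimate(study_id=est.study_id, effect=est.unit_value, se=se))
    return out


def weighted_mean(estimates: list[WeightedEstimate]) -> MetaResult:
    """Inverse-variance pooled mean with its SE and relative weights."""
    if not estimates:
        raise InvalidParameterError("cannot pool an empty set of estimates")
    total_weight = sum(e.weight for e in estimates)
    mean = sum(e.weight * e.effect for e in estimates) / total_weight
    return MetaResult(
        weighted_mean=mean,
        pooled_se=1.0 / math.sqrt(total_weight),
        relative_weights={e.study_id: e.weight / total_weight for e in estimates},
        n_studies=len(estimates),
    )


@dataclass(frozen=True)
class InfluenceRow:
    study_id: str
    relative_weight: float
    loo_mean: float  # pooled mean with this study removed


def influence(estimates: list[WeightedEstimate]) -> list[InfluenceRow]:
    """Relative weight and leave-one-out pooled mean for every study."""
    if len(estimates) < 2:
        raise InvalidParameterError("influence analysis needs at least 2 estimates")
    full = weighted_mean(estimates)
    rows = []
    for est in estimates:
        rest = [e for e in estimates if e is not est]
        rows.append(
            InfluenceRow(
                study_id=est.study_id,
                relative_weight=full.relative_weights[est.study_id],
                loo_mean=weighted_mean(rest).weighted_mean,
            )
        )
    return rows


def quantile_interval(
    values: list[float], mass: float = 0.90
) -> tuple[float, float]:
    """Central empirical quantile interval of a set of values.

    Linear-interpolation quantiles; an approximation used only for
    descriptive reporting of the unit-value spread.
    """
    if not values:
        raise InvalidParameterError("cannot take quantiles of an empty set")
    if not 0 < mass < 1:
        raise InvalidParameterError(f"mass must be in (0, 1), got {mass}")
    import numpy as np

    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(np.asarray(values, dtype=float), [alpha, 1.0 - alpha])
    return float(lo), float(hi)


__all__ = [
    "Z_95",
    "DEFAULT_RELATIVE_SE",
    "WeightedEstimate",
    "MetaResult",
    "InfluenceRow",
    "impute_se",
    "to_weighted",
    "weighted_mean",
    "influence",
    "quantile_interval",
]
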