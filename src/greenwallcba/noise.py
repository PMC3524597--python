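"""Monetisation of noise-level reductions on quiet and exposed façades.

A per-person, per-dB(A), per-year unit price (stated in a reference price
year) is applied to the valued part of a façade's level reduction:

* levels are only valued inside the [cutoff, validity_cap] dB(A) band —
  reductions below the cutoff earn nothing, levels above the cap add
  nothing extra;
* reductions on the quiet side count at ``quiet_side_factor`` of an equal
  reduction on the most exposed side (3 dB quiet-side ≈ 1 dB exposed-side
  at the default 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, ValidationError
from .finance import PriceIndexTable, cpi_adjust

MOST_EXPOSED = "most-exposed"
QUIET = "quiet"
_SIDES = (MOST_EXPOSED, QUIET)


@dataclass(frozen=True)
class NoiseValuationParams:
    """Unit price and validity band of the per-dB noise valuation."""

    unit_price: float = 10.095  # EUR/person/dB(A)/yr at price_year
    price_year: int = 2002
    validity_cap: float = 71.0  # dB(A); levels above add no extra value
    cutoff: float = 45.0  # dB(A); improvements below earn nothing
    quiet_side_factor: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.quiet_side_factor <= 1:
            raise InvalidParameterError(
                f"quiet_side_factor must be in (0, 1], got {self.quiet_side_factor}"
            )
        if not self.cutoff < self.validity_cap:
            raise InvalidParameterError(
                f"cutoff ({self.cutoff}) must be below validity_cap "
                f"({self.validity_cap})"
            )
        if not self.unit_price >= 0:
            raise InvalidParameterError(
                f"unit_price must be >= 0, got {self.unit_price}"
            )


@dataclass(frozen=True)
class FacadeExposure:
    """Noise levels before/after a measure on one façade group."""

    level_before: float
    level_after: float
    side: str = QUIET
    persons: float = 0.0  # may be fractional (apartments x household size)

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValidationError(f"side must be one of {_SIDES}, got {self.side!r}")
        if self.level_after > self.level_before:
            raise ValidationError(
                f"level_after ({self.level_after}) must not exceed level_before "
                f"({self.level_before}) for a benefit"
            )
        if self.persons < 0:
            raise ValidationError(f"persons must be >= 0, got {self.persons}")

    @property
    def reduction_db(self) -> float:
        return self.level_before - self.level_after


def valued_reduction(exposure: FacadeExposure, params: NoiseValuationParams) -> float:
    """Economically valued dB reduction, on the most-exposed-side scale.

    The raw reduction is clamped to the [cutoff, validity_cap] band, then
    quiet-side reductions are scaled by the conversion factor.
    """
    raw = max(
        0.0,
        min(exposure.level_before, params.validity_cap)
        - max(exposure.level_after, params.cutoff),
    )
    if exposure.side == QUIET:
        return raw * params.quiet_side_factor
    return raw


def annual_noise_benefit(
    exposures: list[FacadeExposure],
    params: NoiseValuationParams,
    project_year: int,
    cpi: PriceIndexTable,
) -> float:
    """Total monetised noise benefit across façade groups, EUR/yr."""
    price = cpi_adjust(params.unit_price, params.price_year, project_year, cpi)
    return sum(e.persons * valued_reduction(e, params) * price for e in exposures)


def per_person_unadjusted_benefit(
    delta_db: float,
    params: NoiseValuationParams,
    project_year: int,
    cpi: PriceIndexTable,
) -> float:
    """EUR/person/yr for a nominal reduction, before any quiet-side scaling.

    A reporting convenience: no clamping or side conversion is applied.
    """
    if delta_db < 0:
        raise InvalidParameterError(f"delta_db must be >= 0, got {delta_db}")
    return delta_db * cpi_adjust(params.unit_price, params.price_year, project_year, cpi)


__all__ = [
    "MOST_EXPOSED",
    "QUIET",
    "NoiseValuationParams",
    "FacadeExposure",
    "valued_reduction",
    "annual_noise_benefit",
    "per_person_unadjusted_benefit",
]
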