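"""Discounting, annuitization, price-index updating and currency conversion.

All downstream stages (value transfer, noise and amenity monetisation,
scenario cost-benefit analysis) express money flows as constant annual
amounts.  This module provides the primitives that make flows from
different years, currencies and payment schedules comparable:

* :func:`annuity_factor` / :func:`annualize` — present value <-> constant
  annual amount at a given rate, horizon and payment timing;
* :func:`pv_recurring_investment` — present value of an investment that is
  repeated every ``cycle`` years over a project horizon;
* :func:`cpi_adjust` — restate an amount between price-index years;
* :func:`fx_to_eur` — convert local-currency amounts to EUR at the rate of
  the data year.

Two payment-timing conventions coexist deliberately: ordinary (end-of-year)
annuities for property annuitization and annuity-due (start-of-year) for
project flows.  The convention is always explicit in :class:`DiscountSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError, MissingIndexError, MissingRateError

#: Ordinary annuity: payments fall at the end of each year.
END_OF_YEAR = "end-of-year"
#: Annuity-due: payments fall at the start of each year.
START_OF_YEAR = "start-of-year"

_TIMINGS = (END_OF_YEAR, START_OF_YEAR)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate, integer horizon and payment-timing convention."""

    rate: float
    horizon: int
    timing: str = END_OF_YEAR

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InvalidParameterError(f"discount rate must be > 0, got {self.rate}")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise InvalidParameterError(
                f"horizon must be an integer >= 1, got {self.horizon}"
            )
        if self.timing not in _TIMINGS:
            raise InvalidParameterError(
                f"timing must be one of {_TIMINGS}, got {self.timing!r}"
            )


@dataclass(frozen=True)
class PriceIndexTable:
    """Consumer price index values keyed by year (any consistent scale)."""

    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, value in self.values.items():
            if not value > 0:
                raise InvalidParameterError(
                    f"price index for {year} must be > 0, got {value}"
                )

    def index(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise MissingIndexError(f"no price index for year {year}") from None

    def factor(self, from_year: int, to_year: int) -> float:
        """Multiplicative update factor from ``from_year`` to ``to_year``."""
        return self.index(to_year) / self.index(from_year)


@dataclass(frozen=True)
class FxTable:
    """EUR per unit of local currency, keyed by (currency code, year)."""

    rates: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rate in self.rates.items():
            if not rate > 0:
                raise InvalidParameterError(f"fx rate for {key} must be > 0, got {rate}")

    def rate(self, currency: str, year: int) -> float:
        try:
            return self.rates[(currency, year)]
        except KeyError:
            raise MissingRateError(
                f"no EUR exchange rate for {currency} in {year}"
            ) from None


def annuity_factor(spec: DiscountSpec) -> float:
    """Factor converting a present value into a constant annual amount.

    End-of-year timing gives the ordinary factor ``(1 - (1+r)^-T) / r``;
    start-of-year timing multiplies it by ``(1+r)``.  Dividing a present
    value by the factor yields the equivalent constant annual amount.
    """
    r, t = spec.rate, spec.horizon
    # -expm1(-t*log1p(r)) == 1 - (1+r)^-t, stable for rates near zero
    factor = -math.expm1(-t * math.log1p(r)) / r
    if spec.timing == START_OF_YEAR:
        factor *= 1.0 + r
    return factor


def annualize(present_value: float, spec: DiscountSpec) -> float:
    """Constant annual amount equivalent to ``present_value`` under ``spec``."""
    if present_value < 0:
        raise InvalidParameterError(
            f"present value must be >= 0, got {present_value}"
        )
    return present_value / annuity_factor(spec)


def pv_recurring_investment(
    unit_cost: float,
    cycle: int,
    horizon: int,
    rate: float,
    timing: str = START_OF_YEAR,
) -> float:
    """Present value of an outlay repeated every ``cycle`` years.

    Re-investment epochs are t = 0, cycle, 2*cycle, ... < horizon.  No
    salvage value or terminal correction is applied at the horizon.  Under
    end-of-year timing each outlay is shifted one year later.
    """
    if int(cycle) != cycle or cycle < 1:
        raise InvalidParameterError(f"cycle must be an integer >= 1, got {cycle}")
    if cycle > horizon:
        raise InvalidParameterError(
            f"cycle ({cycle}) must not exceed horizon ({horizon})"
        )
    # validate rate/horizon/timing through the spec type
    DiscountSpec(rate=rate, horizon=horizon, timing=timing)
    shift = 0 if timing == START_OF_YEAR else 1
    return sum(
        unit_cost * (1.0 + rate) ** -(t + shift) for t in range(0, horizon, int(cycle))
    )


def cpi_adjust(
    amount: float, from_year: int, to_year: int, table: PriceIndexTable
) -> float:
    """Restate ``amount`` from ``from_year`` prices to ``to_year`` prices."""
    return amount * table.factor(from_year, to_year)


def fx_to_eur(amount: float, currency: str, year: int, table: FxTable) -> float:
    """Convert a local-currency amount to EUR at the given year's rate."""
    return amount * table.rate(currency, year)


__all__ = [
    "END_OF_YEAR",
    "START_OF_YEAR",
    "DiscountSpec",
    "PriceIndexTable",
    "FxTable",
    "annuity_factor",
    "annualize",
    "pv_recurring_investment",
    "cpi_adjust",
    "fx_to_eur",
    "MissingIndexError",
    "MissingRateError",
]
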