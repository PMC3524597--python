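"""Benefit transfer of hedonic greenery valuations to per-m² unit values.

Each reviewed study reports the percentage effect of roof/wall greenery on
a property price or an annual rent, in some currency and data year.  The
transfer chain turns that into a common unit value: EUR per m² of greenery
per household per year, at the base price-index year.

Chain per record::

    price --(annuitize property prices)--> annual value (local currency)
          --(x premium midpoint)--------> greenery annual value
          --(x EUR/currency of the data year)
          --(x CPI factor data year -> base year)
          --(/ greenery area)-----------> unit value  [EUR/m²/household/yr]

Rents pass through the annuitization step unchanged.  A ``premium_base``
flag records whether the percentage applies to the annuity (the default)
or to the raw price — some source studies quote land-price effects that
only reproduce when multiplied against the raw price.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError, ValidationError
from .finance import (
    END_OF_YEAR,
    DiscountSpec,
    FxTable,
    PriceIndexTable,
    annualize,
    cpi_adjust,
    fx_to_eur,
)

PROPERTY_PRICE = "property-price"
ANNUAL_RENT = "annual-rent"
_PRICE_KINDS = (PROPERTY_PRICE, ANNUAL_RENT)
_PREMIUM_BASES = ("annuity", PROPERTY_PRICE)


# --------------------------------------------------------------------------
# uncertainty statements attached to a study's premium estimate
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalUncertainty:
    """Premium reported as a (lo, hi) percent interval."""

    lo_pct: float
    hi_pct: float

    kind = "interval"

    def __post_init__(self) -> None:
        if not self.lo_pct < self.hi_pct:
            raise ValidationError(
                f"interval must satisfy lo < hi, got ({self.lo_pct}, {self.hi_pct})"
            )

    @property
    def midpoint_pct(self) -> float:
        return 0.5 * (self.lo_pct + self.hi_pct)


@dataclass(frozen=True)
class ReportedRelativeSE:
    """Standard error reported by the source study, as SE / point estimate."""

    relative_se: float

    kind = "reported-se"

    def __post_init__(self) -> None:
        if not self.relative_se > 0:
            raise ValidationError(
                f"relative SE must be > 0, got {self.relative_se}"
            )


@dataclass(frozen=True)
class NoUncertainty:
    """No uncertainty statement in the source study."""

    kind = "none"


Uncertainty = IntervalUncertainty | ReportedRelativeSE | NoUncertainty


# --------------------------------------------------------------------------
# record / config / estimate types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HedonicStudyRecord:
    """Raw economic facts extracted from one reviewed valuation study.

    ``premium_pct`` is the point (midpoint) greenery percentage effect; for
    interval uncertainties it must equal the interval midpoint.
    """

    study_id: str
    data_year: int
    location: str
    currency: str
    price_kind: str
    price: float
    premium_pct: float
    greenery_area: float
    premium_base: str = "annuity"
    uncertainty: Uncertainty = field(default_factory=NoUncertainty)

    def __post_init__(self) -> None:
        if self.price_kind not in _PRICE_KINDS:
            raise ValidationError(
                f"price_kind must be one of {_PRICE_KINDS}, got {self.price_kind!r}",
                context=self.study_id,
            )
        if self.premium_base not in _PREMIUM_BASES:
            raise ValidationError(
                f"premium_base must be one of {_PREMIUM_BASES}, "
                f"got {self.premium_base!r}",
                context=self.study_id,
            )
        if not self.price > 0:
            raise ValidationError(f"price must be > 0, got {self.price}", self.study_id)
        if not self.greenery_area > 0:
            raise ValidationError(
                f"greenery_area must be > 0, got {self.greenery_area}", self.study_id
            )
        if not self.premium_pct > 0:
            raise ValidationError(
                f"premium midpoint must be > 0, got {self.premium_pct}", self.study_id
            )
        if isinstance(self.uncertainty, IntervalUncertainty):
            mid = self.uncertainty.midpoint_pct
            if not math.isclose(mid, self.premium_pct, rel_tol=1e-9, abs_tol=1e-9):
                raise ValidationError(
                    f"premium_pct ({self.premium_pct}) must equal the interval "
                    f"midpoint ({mid})",
                    context=self.study_id,
                )


@dataclass(frozen=True)
class TransferConfig:
    """Shared assumptions of the transfer: discounting, tables, base year."""

    fx: FxTable
    cpi: PriceIndexTable
    property_discount: DiscountSpec = DiscountSpec(0.05, 50, END_OF_YEAR)
    base_year: int = 2010
    household_size: float = 2.4

    def __post_init__(self) -> None:
        if not self.household_size > 0:
            raise InvalidParameterError(
                f"household_size must be > 0, got {self.household_size}"
            )


@dataclass(frozen=True)
class UnitValueEstimate:
    """Per-m² per-household-per-year amenity value at the base year."""

    study_id: str
    eur_base_value: float  # EUR/household/yr at base year
    unit_value: float  # EUR/m²/household/yr
    area: float
    uncertainty: Uncertainty = field(default_factory=NoUncertainty)
    se: float | None = None  # on the unit-value scale, filled by imputation

    def with_se(self, se: float) -> "UnitValueEstimate":
        return replace(self, se=se)


# --------------------------------------------------------------------------
# transfer operations
# --------------------------------------------------------------------------


def annuitize_record(record: HedonicStudyRecord, config: TransferConfig) -> float:
    """Annual-value equivalent of the record's price, in local currency.

    Property prices are annuitized with the configured discount spec;
    annual rents pass through unchanged.
    """
    if record.price_kind == ANNUAL_RENT:
        return record.price
    return annualize(record.price, config.property_discount)


def greenery_annual_value(record: HedonicStudyRecord, config: TransferConfig) -> float:
    """Greenery share of the annual value, local currency per household/yr."""
    base = (
        record.price
        if record.premium_base == PROPERTY_PRICE
        else annuitize_record(record, config)
    )
    return base * record.premium_pct / 100.0


def to_unit_value(
    record: HedonicStudyRecord, config: TransferConfig
) -> UnitValueEstimate:
    """Full transfer of one record to a base-year EUR per-m² unit value."""
    local_annual = greenery_annual_value(record, config)
    eur_data_year = fx_to_eur(local_annual, record.currency, record.data_year, config.fx)
    eur_base = cpi_adjust(eur_data_year, record.data_year, config.base_year, config.cpi)
    return UnitValueEstimate(
        study_id=record.study_id,
        eur_base_value=eur_base,
        unit_value=eur_base / record.greenery_area,
        area=record.greenery_area,
        uncertainty=record.uncertainty,
    )


def transfer_all(
    records: list[HedonicStudyRecord], config: TransferConfig
) -> list[UnitValueEstimate]:
    return [to_unit_value(r, config) for r in records]


def per_person(value: float, config: TransferConfig) -> float:
    """Convert a per-household value to a per-person value."""
    return value / config.household_size


def summarize_unit_values(
    estimates: list[UnitValueEstimate] | list[float], exclude_max: bool = False
) -> float:
    """Arithmetic mean of unit values, optionally dropping the single maximum."""
    values = [
        e.unit_value if isinstance(e, UnitValueEstimate) else float(e)
        for e in estimates
    ]
    if not values:
        raise InvalidParameterError("cannot summarize an empty set of estimates")
    if exclude_max:
        if len(values) == 1:
            raise InvalidParameterError(
                "cannot exclude the maximum from a single estimate"
            )
        values = sorted(values)[:-1]
    return sum(values) / len(values)


__all__ = [
    "PROPERTY_PRICE",
    "ANNUAL_RENT",
    "IntervalUncertainty",
    "ReportedRelativeSE",
    "NoUncertainty",
    "Uncertainty",
    "HedonicStudyRecord",
    "TransferConfig",
    "UnitValueEstimate",
    "annuitize_record",
    "greenery_annual_value",
    "to_unit_value",
    "transfer_all",
    "per_person",
    "summarize_unit_values",
]
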