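"""Monetisation of non-acoustic amenity/aesthetic benefits of a green wall.

The benefit is bilinear: wall area times a per-m² per-person annual unit
value (CPI-updated from its value year to the project year) times the
number of beneficiary persons.  Amenity benefits are simply added to noise
benefits at the CBA layer; no interaction is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, ValidationError
from .finance import PriceIndexTable, cpi_adjust


@dataclass(frozen=True)
class AmenityParams:
    unit_value: float  # EUR/m²/person/yr at value_year
    value_year: int = 2010

    def __post_init__(self) -> None:
        if self.unit_value < 0:
            raise InvalidParameterError(
                f"unit_value must be >= 0, got {self.unit_value}"
            )


@dataclass(frozen=True)
class BeneficiaryRoster:
    """Persons benefiting from the view/use of the wall; may be fractional."""

    resident_persons: float = 0.0  # in the treated building
    external_persons: float = 0.0  # direct view from other buildings

    def __post_init__(self) -> None:
        if self.resident_persons < 0 or self.external_persons < 0:
            raise ValidationError("roster person counts must be >= 0")

    @property
    def total_persons(self) -> float:
        return self.resident_persons + self.external_persons


def annual_amenity_benefit(
    area: float,
    roster: BeneficiaryRoster,
    params: AmenityParams,
    project_year: int,
    cpi: PriceIndexTable,
) -> float:
    """Total amenity benefit, EUR/yr."""
    if area < 0:
        raise InvalidParameterError(f"area must be >= 0, got {area}")
    unit = cpi_adjust(params.unit_value, params.value_year, project_year, cpi)
    return area * unit * roster.total_persons


__all__ = ["AmenityParams", "BeneficiaryRoster", "annual_amenity_benefit"]
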