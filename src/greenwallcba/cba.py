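"""Scenario cost-benefit assembly: annualized line items and B/C ratios.

Costs are incremental against a wall without greenery: a per-m² investment
that recurs every lifetime over the project horizon (annualized with the
project discount spec) plus annual per-m² maintenance.  Benefits are the
noise-attenuation and amenity streams.  The B/C ratio is computed from
unrounded line items; table rendering rounds for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .amenity import AmenityParams, BeneficiaryRoster, annual_amenity_benefit
from .errors import UndefinedRatioError, ValidationError
from .finance import (
    START_OF_YEAR,
    DiscountSpec,
    PriceIndexTable,
    annualize,
    pv_recurring_investment,
)
from .noise import FacadeExposure, NoiseValuationParams, annual_noise_benefit


@dataclass(frozen=True)
class GreenWallScenario:
    """One demonstration project: geometry, costs, exposures, beneficiaries."""

    name: str
    area: float  # m² of vegetated façade
    cpi: PriceIndexTable
    invest_unit_cost: float = 500.0  # EUR/m²
    invest_lifetime: int = 10  # yr between re-investments
    maintenance_unit_cost: float = 25.0  # EUR/m²/yr
    cost_year: int = 2011
    project_discount: DiscountSpec = DiscountSpec(0.03, 40, START_OF_YEAR)
    project_year: int = 2011
    exposures: tuple[FacadeExposure, ...] = ()
    roster: BeneficiaryRoster = field(default_factory=BeneficiaryRoster)
    noise_params: NoiseValuationParams = field(default_factory=NoiseValuationParams)
    amenity_params: AmenityParams = field(default_factory=lambda: AmenityParams(0.0))
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError(f"area must be > 0, got {self.area}", self.name)
        if self.invest_unit_cost < 0 or self.maintenance_unit_cost < 0:
            raise ValidationError("unit costs must be >= 0", self.name)
        object.__setattr__(self, "exposures", tuple(self.exposures))
        object.__setattr__(self, "notes", tuple(self.notes))


@dataclass(frozen=True)
class CbaResult:
    """Annualized line items (EUR/yr) and the benefit-cost ratio."""

    name: str
    annual_investment: float
    annual_maintenance: float
    noise_benefit: float
    amenity_benefit: float
    notes: tuple[str, ...] = ()

    @property
    def total_benefits(self) -> float:
        return self.noise_benefit + self.amenity_benefit

    @property
    def total_costs(self) -> float:
        return self.annual_investment + self.annual_maintenance

    @property
    def bc_ratio(self) -> float:
        if self.total_costs == 0:
            raise UndefinedRatioError(f"{self.name}: total costs are zero")
        return self.total_benefits / self.total_costs


def annual_costs(scenario: GreenWallScenario) -> tuple[float, float]:
    """(annualized investment, annual maintenance) in EUR/yr."""
    spec = scenario.project_discount
    pv_per_m2 = pv_recurring_investment(
        scenario.invest_unit_cost,
        scenario.invest_lifetime,
        spec.horizon,
        spec.rate,
        spec.timing,
    )
    investment = scenario.area * annualize(pv_per_m2, spec)
    maintenance = scenario.area * scenario.maintenance_unit_cost
    return investment, maintenance


def run_cba(scenario: GreenWallScenario) -> CbaResult:
    """Assemble all annualized line items for one scenario."""
    investment, maintenance = annual_costs(scenario)
    noise = annual_noise_benefit(
        list(scenario.exposures),
        scenario.noise_params,
        scenario.project_year,
        scenario.cpi,
    )
    amenity = annual_amenity_benefit(
        scenario.area,
        scenario.roster,
        scenario.amenity_params,
        scenario.project_year,
        scenario.cpi,
    )
    result = CbaResult(
        name=scenario.name,
        annual_investment=investment,
        annual_maintenance=maintenance,
        noise_benefit=noise,
        amenity_benefit=amenity,
        notes=scenario.notes,
    )
    if result.total_costs == 0:
        raise UndefinedRatioError(f"{scenario.name}: total costs are zero")
    return result


def benefit_share(result: CbaResult) -> float:
    """Ratio of amenity to noise benefits."""
    if result.noise_benefit == 0:
        raise UndefinedRatioError(f"{result.name}: noise benefit is zero")
    return result.amenity_benefit / result.noise_benefit


__all__ = [
    "GreenWallScenario",
    "CbaResult",
    "annual_costs",
    "run_cba",
    "benefit_share",
]
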