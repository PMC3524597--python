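"""Synthetic inputs with known ground truth, plus packaged fixtures.

Two generators make every pipeline stage testable offline:

* :func:`gen_hedonic_studies` builds study records whose transferred unit
  values are draws around a known true value with known standard errors,
  by inverting the transfer chain on the percentage scale — so the real
  currency/CPI/annuitization code paths are exercised;
* :func:`gen_scenario` builds a random green-wall scenario together with
  its expected CBA line items computed by an independent straight-line
  arithmetic oracle (deliberately sharing no code with the CBA modules,
  so pipeline bugs cannot self-validate).

:func:`load_fixture` exposes the packaged in-study inputs by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amenity import AmenityParams, BeneficiaryRoster
from .cba import GreenWallScenario
from .errors import InvalidParameterError, UnknownFixtureError
from .finance import (
    END_OF_YEAR,
    START_OF_YEAR,
    DiscountSpec,
    PriceIndexTable,
    annuity_factor,
)
from .io import (
    ParameterTables,
    load_parameter_tables,
    packaged_data_path,
    read_scenario,
    read_studies,
)
from .noise import MOST_EXPOSED, QUIET, FacadeExposure, NoiseValuationParams
from .transfer import (
    ANNUAL_RENT,
    PROPERTY_PRICE,
    HedonicStudyRecord,
    IntervalUncertainty,
    NoUncertainty,
    ReportedRelativeSE,
)

# --------------------------------------------------------------------------
# hedonic study generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticStudySpec:
    true_unit_value: float  # EUR/m²/household/yr, the latent truth
    n_studies: int
    se_range: tuple[float, float] = (0.1, 0.6)  # relative SEs
    kind_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # interval/reported/none
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_unit_value > 0:
            raise InvalidParameterError("true_unit_value must be > 0")
        if self.n_studies < 1:
            raise InvalidParameterError("n_studies must be >= 1")
        lo, hi = self.se_range
        if not 0 < lo <= hi:
            raise InvalidParameterError(f"se_range must satisfy 0 < lo <= hi, got {self.se_range}")
        if abs(sum(self.kind_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.kind_mix):
            raise InvalidParameterError("kind_mix proportions must be >= 0 and sum to 1")


@dataclass(frozen=True)
class StudyTruth:
    """Latent truth emitted alongside each generated record."""

    study_id: str
    true_unit_value: float
    se: float  # on the unit-value scale
    observed_unit_value: float  # the noisy draw the record encodes


def gen_hedonic_studies(
    spec: SyntheticStudySpec, tables: ParameterTables | None = None
) -> tuple[list[HedonicStudyRecord], list[StudyTruth]]:
    """Generate fully valid study records around a known true unit value.

    Each study's observed unit value is drawn from
    ``Normal(truth, (rel_se * truth)^2)`` (redrawn while not positive),
    then the premium percentage that reproduces it through the real
    transfer chain is back-solved.  Currency/year pairs are sampled from
    the shipped parameter tables.
    """
    if tables is None:
        tables = load_parameter_tables()
    rng = np.random.default_rng(spec.seed)
    base_year = 2010
    disc = DiscountSpec(0.05, 50, END_OF_YEAR)
    pairs = sorted(
        (cur, yr)
        for (cur, yr) in tables.fx.rates
        if yr in tables.cpi.values and base_year in tables.cpi.values
    )
    kinds = ["interval", "reported", "none"]

    records: list[HedonicStudyRecord] = []
    truths: list[StudyTruth] = []
    for i in range(spec.n_studies):
        kind = kinds[rng.choice(3, p=list(spec.kind_mix))]
        rel = float(rng.uniform(*spec.se_range))
        if kind == "none":
            rel = 0.5  # what the imputation rule will assume
        elif kind == "interval":
            rel = min(rel, 0.45)  # keeps the implied interval strictly positive
        se = rel * spec.true_unit_value
        while True:
            observed = float(rng.normal(spec.true_unit_value, se))
            if observed > 0.01 * spec.true_unit_value:
                break

        currency, year = pairs[rng.integers(len(pairs))]
        price_kind = PROPERTY_PRICE if rng.random() < 0.7 else ANNUAL_RENT
        price = float(
            rng.uniform(50_000, 500_000)
            if price_kind == PROPERTY_PRICE
            else rng.uniform(2_000, 30_000)
        )
        area = float(rng.uniform(20, 100))
        annuity = price / annuity_factor(disc) if price_kind == PROPERTY_PRICE else price
        fx_rate = tables.fx.rate(currency, year)
        cpi_factor = tables.cpi.factor(year, base_year)
        premium_pct = 100.0 * observed * area / (fx_rate * cpi_factor * annuity)

        if kind == "interval":
            half = 1.96 * rel * premium_pct
            uncertainty = IntervalUncertainty(premium_pct - half, premium_pct + half)
        elif kind == "reported":
            uncertainty = ReportedRelativeSE(rel)
        else:
            uncertainty = NoUncertainty()

        study_id = f"synth_{i:04d}"
        records.append(
            HedonicStudyRecord(
                study_id=study_id,
                data_year=year,
                location="synthetic",
                currency=currency,
                price_kind=price_kind,
                price=price,
                premium_pct=premium_pct,
                greenery_area=area,
                uncertainty=uncertainty,
            )
        )
        truths.append(
            StudyTruth(
                study_id=study_id,
                true_unit_value=spec.true_unit_value,
                se=se,
                observed_unit_value=observed,
            )
        )
    return records, truths


# --------------------------------------------------------------------------
# scenario generator with an independent arithmetic oracle
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticScenarioSpec:
    seed: int = 0
    area_range: tuple[float, float] = (20.0, 500.0)
    invest_cost_range: tuple[float, float] = (100.0, 1000.0)
    maintenance_cost_range: tuple[float, float] = (5.0, 50.0)
    db_range: tuple[float, float] = (0.5, 8.0)
    persons_range: tuple[float, float] = (10.0, 200.0)
    amenity_unit_range: tuple[float, float] = (0.0, 3.0)
    n_exposure_groups: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        for name in (
            "area_range",
            "invest_cost_range",
            "maintenance_cost_range",
            "db_range",
            "persons_range",
        ):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidParameterError(f"{name} must satisfy 0 < lo <= hi")


def gen_scenario(
    spec: SyntheticScenarioSpec,
) -> tuple[GreenWallScenario, dict[str, float]]:
    """Random scenario plus its expected CBA computed by plain arithmetic.

    Exposure levels are kept strictly inside the valuation band so the
    oracle needs no clamping logic; the oracle duplicates the annuity and
    discounting arithmetic with explicit loops and shares no code with the
    finance/CBA modules.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform

    rate = float(u(0.01, 0.08))
    horizon = int(rng.integers(20, 51))
    lifetime = int(rng.integers(5, horizon + 1))
    timing = START_OF_YEAR if rng.random() < 0.5 else END_OF_YEAR
    area = float(u(*spec.area_range))
    invest = float(u(*spec.invest_cost_range))
    maintenance = float(u(*spec.maintenance_cost_range))
    factor = float(u(0.2, 1.0))
    unit_price = float(u(5.0, 20.0))
    cutoff, cap = 45.0, 71.0
    cpi = {2002: float(u(80, 100)), 2010: float(u(100, 120)), 2011: float(u(110, 125))}

    exposures = []
    for _ in range(int(rng.integers(spec.n_exposure_groups[0], spec.n_exposure_groups[1] + 1))):
        before = float(u(50.0, 70.0))
        delta = float(u(spec.db_range[0], min(spec.db_range[1], before - cutoff - 1.0)))
        exposures.append(
            FacadeExposure(
                level_before=before,
                level_after=before - delta,
                side=QUIET if rng.random() < 0.7 else MOST_EXPOSED,
                persons=float(u(*spec.persons_range)),
            )
        )
    amenity_unit = float(u(*spec.amenity_unit_range))
    resident = float(u(*spec.persons_range))
    external = float(u(0.0, 30.0))

    scenario = GreenWallScenario(
        name=f"synthetic-{spec.seed}",
        area=area,
        cpi=PriceIndexTable(cpi),
        invest_unit_cost=invest,
        invest_lifetime=lifetime,
        maintenance_unit_cost=maintenance,
        cost_year=2011,
        project_discount=DiscountSpec(rate, horizon, timing),
        project_year=2011,
        exposures=tuple(exposures),
        roster=BeneficiaryRoster(resident_persons=resident, external_persons=external),
        noise_params=NoiseValuationParams(
            unit_price=unit_price,
            price_year=2002,
            validity_cap=cap,
            cutoff=cutoff,
            quiet_side_factor=factor,
        ),
        amenity_params=AmenityParams(unit_value=amenity_unit, value_year=2010),
    )

    # ---- independent oracle: straight-line arithmetic only ----
    if timing == START_OF_YEAR:
        af = 0.0
        for t in range(horizon):
            af += (1.0 + rate) ** -t
    else:
        af = 0.0
        for t in range(1, horizon + 1):
            af += (1.0 + rate) ** -t
    shift = 0 if timing == START_OF_YEAR else 1
    pv = 0.0
    t = 0
    while t < horizon:
        pv += invest * (1.0 + rate) ** -(t + shift)
        t += lifetime
    annual_investment = area * pv / af
    annual_maintenance = area * maintenance

    price_project = unit_price * cpi[2011] / cpi[2002]
    noise_benefit = 0.0
    for exp in exposures:
        delta = exp.level_before - exp.level_after
        side_factor = factor if exp.side == QUIET else 1.0
        noise_benefit += exp.persons * delta * side_factor * price_project
    amenity_benefit = area * amenity_unit * (cpi[2011] / cpi[2010]) * (resident + external)

    total_benefits = noise_benefit + amenity_benefit
    total_costs = annual_investment + annual_maintenance
    expected = {
        "annual_investment": annual_investment,
        "annual_maintenance": annual_maintenance,
        "noise_benefit": noise_benefit,
        "amenity_benefit": amenity_benefit,
        "total_benefits": total_benefits,
        "total_costs": total_costs,
        "bc_ratio": total_benefits / total_costs,
    }
    return scenario, expected


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "table1_studies.csv",
    "table2": "table1_studies.csv",  # same records; table2 adds the weighting
    "demo_3m": "scenarios/demo_3m_high.yaml",
    "demo_19m": "scenarios/demo_19m_high.yaml",
    "demo_3m_low": "scenarios/demo_3m_low.yaml",
    "demo_19m_low": "scenarios/demo_19m_low.yaml",
}


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table1`` / ``table2`` return the list of study records;
    ``demo_3m`` / ``demo_19m`` (and their ``_low`` variants) return a
    ``(GreenWallScenario, McSpec | None)`` pair.
    """
    try:
        rel = _FIXTURE_FILES[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURE_FILES)}"
        ) from None
    path = packaged_data_path(rel)
    if rel.endswith(".csv"):
        return read_studies(path)
    tables = load_parameter_tables()
    return read_scenario(path, tables.cpi)


__all__ = [
    "SyntheticStudySpec",
    "SyntheticScenarioSpec",
    "StudyTruth",
    "gen_hedonic_studies",
    "gen_scenario",
    "load_fixture",
]
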