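"""Monte Carlo sensitivity analysis of the benefit-cost ratio.

Named scenario quantities are perturbed independently, each drawn from a
normal distribution centred on its point value with standard deviation
``fractional uncertainty x point value``, truncated below at a small
positive multiple of the point value so no draw is negative or nearly
zero.  The perturbed scenario is pushed through the deterministic CBA for
every draw; the result is the empirical B/C distribution and its central
quantile band.

Perturbation keys (all optional; unlisted quantities pass through):

* ``amenity_value``     — the amenity unit value;
* ``noise_effect``      — each façade group's dB reduction;
* ``investment_cost``   — the per-m² investment unit cost;
* ``maintenance_cost``  — the per-m² annual maintenance cost;
* ``beneficiaries``     — every person count (exposures and roster).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .amenity import BeneficiaryRoster
from .cba import GreenWallScenario, run_cba
from .errors import InvalidParameterError
from .noise import FacadeExposure

PERTURBATION_KEYS = (
    "amenity_value",
    "noise_effect",
    "investment_cost",
    "maintenance_cost",
    "beneficiaries",
)

#: default fractional uncertainties
DEFAULT_PERTURBATIONS = {
    "amenity_value": 0.50,
    "noise_effect": 0.30,
    "investment_cost": 0.30,
    "maintenance_cost": 0.30,
    "beneficiaries": 0.15,
}


@dataclass(frozen=True)
class McSpec:
    draws: int = 10_000
    seed: int = 0
    perturbations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERTURBATIONS)
    )
    lower_truncation: float = 0.01  # minimum admissible multiple of the point value
    band: float = 0.90  # central probability mass of the reported band

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise InvalidParameterError(f"draws must be >= 1, got {self.draws}")
        if not 0 < self.band < 1:
            raise InvalidParameterError(f"band must be in (0, 1), got {self.band}")
        unknown = set(self.perturbations) - set(PERTURBATION_KEYS)
        if unknown:
            raise InvalidParameterError(
                f"unknown perturbation keys {sorted(unknown)}; "
                f"known keys: {PERTURBATION_KEYS}"
            )
        for key, frac in self.perturbations.items():
            if frac < 0:
                raise InvalidParameterError(
                    f"fractional uncertainty for {key!r} must be >= 0, got {frac}"
                )


@dataclass(frozen=True)
class McResult:
    bc_samples: np.ndarray
    point_estimate: float
    band_low: float
    band_high: float
    band: float

    @property
    def median(self) -> float:
        return float(np.median(self.bc_samples))

    def share_above(self, threshold: float) -> float:
        """Fraction of draws with B/C strictly above ``threshold``."""
        return float(np.mean(self.bc_samples > threshold))


def _draw_truncated(
    rng: np.random.Generator, point: float, frac: float, lower_multiple: float
) -> float:
    """One truncated-normal draw around ``point`` by rejection sampling.

    Acceptance is ~99.9% at the fractional uncertainties used here, so the
    loop is cheap and deterministic given the generator state.
    """
    if point == 0 or frac == 0:
        return point
    sd = frac * point
    lower = lower_multiple * point
    while True:
        value = rng.normal(point, sd)
        if value >= lower:
            return value


def sample_perturbed_scenario(
    scenario: GreenWallScenario, spec: McSpec, rng: np.random.Generator
) -> GreenWallScenario:
    """One perturbed copy of the scenario; draw order is fixed for determinism."""
    frac = spec.perturbations
    lower = spec.lower_truncation

    amenity = scenario.amenity_params
    if "amenity_value" in frac:
        amenity = replace(
            amenity,
            unit_value=_draw_truncated(
                rng, amenity.unit_value, frac["amenity_value"], lower
            ),
        )

    exposures = []
    for exp in scenario.exposures:
        delta = exp.reduction_db
        if "noise_effect" in frac:
            delta = _draw_truncated(rng, delta, frac["noise_effect"], lower)
        persons = exp.persons
        if "beneficiaries" in frac:
            persons = _draw_truncated(rng, persons, frac["beneficiaries"], lower)
        exposures.append(
            FacadeExposure(
                level_before=exp.level_before,
                level_after=exp.level_before - delta,
                side=exp.side,
                persons=persons,
            )
        )

    invest = scenario.invest_unit_cost
    if "investment_cost" in frac:
        invest = _draw_truncated(rng, invest, frac["investment_cost"], lower)
    maintenance = scenario.maintenance_unit_cost
    if "maintenance_cost" in frac:
        maintenance = _draw_truncated(rng, maintenance, frac["maintenance_cost"], lower)

    roster = scenario.roster
    if "beneficiaries" in frac:
        roster = BeneficiaryRoster(
            resident_persons=_draw_truncated(
                rng, roster.resident_persons, frac["beneficiaries"], lower
            ),
            external_persons=_draw_truncated(
                rng, roster.external_persons, frac["beneficiaries"], lower
            ),
        )

    return replace(
        scenario,
        amenity_params=amenity,
        exposures=tuple(exposures),
        invest_unit_cost=invest,
        maintenance_unit_cost=maintenance,
        roster=roster,
    )


def simulate(scenario: GreenWallScenario, spec: McSpec) -> McResult:
    """Run the CBA under ``spec.draws`` perturbed input sets."""
    rng = np.random.default_rng(spec.seed)
    point = run_cba(scenario).bc_ratio
    samples = np.empty(spec.draws, dtype=float)
    for i in range(spec.draws):
        perturbed = sample_perturbed_scenario(scenario, spec, rng)
        samples[i] = run_cba(perturbed).bc_ratio
    alpha = (1.0 - spec.band) / 2.0
    # order-statistic quantiles: band endpoints are actual samples
    band_low = float(np.quantile(samples, alpha, method="lower"))
    band_high = float(np.quantile(samples, 1.0 - alpha, method="higher"))
    return McResult(
        bc_samples=samples,
        point_estimate=point,
        band_low=band_low,
        band_high=band_high,
        band=spec.band,
    )


def plot_band(result: McResult, path: str, title: str | None = None) -> None:
    """Histogram of simulated B/C values with the quantile band marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(result.bc_samples, bins=80, color="#4a7c59", alpha=0.8)
    ax.axvspan(
        result.band_low,
        result.band_high,
        color="#cdeac0",
        alpha=0.4,
        label=f"{result.band:.0%} band",
    )
    ax.axvline(result.point_estimate, color="black", lw=1.2, label="point estimate")
    ax.set_xlabel("benefit-cost ratio")
    ax.set_ylabel("draws")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "PERTURBATION_KEYS",
    "DEFAULT_PERTURBATIONS",
    "McSpec",
    "McResult",
    "sample_perturbed_scenario",
    "simulate",
    "plot_band",
]
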