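"""Policy scenarios: investment fractions and policy levers.

Three presets follow the study design: Scenario 0 is business-as-usual with
zero investment; Scenario 1 invests 1% of the previous year's adjusted GDP
in ecosystem restoration and 1% in green/blue infrastructure; Scenario 2
keeps the investment and adds the policy package (55% emission cut, full
waste treatment, +10% employment, -25% vehicles, -36% vehicle emissions).
All levers are constant over the whole run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .params import ParameterSet


@dataclass(frozen=True)
class ScenarioSpec:
    name: str = "custom"
    invest_frac_restoration: float = 0.0  # fraction of lagged adjusted GDP /yr
    invest_frac_gi: float = 0.0           # fraction of lagged adjusted GDP /yr
    emission_cut: float = 0.0             # fractional cut of per-capita emissions
    waste_full_treatment: bool = False    # treat 100% of generated waste
    employment_boost: float = 0.0         # relative employment-rate increase
    vehicle_cut: float = 0.0              # fractional cut of the vehicle fleet
    vehicle_emission_cut: float = 0.0     # fractional cut of per-vehicle emissions

    def __post_init__(self) -> None:
        for f in (
            "invest_frac_restoration",
            "invest_frac_gi",
            "emission_cut",
            "employment_boost",
            "vehicle_cut",
            "vehicle_emission_cut",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")


def preset(n: int) -> ScenarioSpec:
    """Return one of the three study scenarios."""
    if n == 0:
        return ScenarioSpec(name="scenario0")
    if n == 1:
        return ScenarioSpec(
            name="scenario1",
            invest_frac_restoration=0.01,
            invest_frac_gi=0.01,
        )
    if n == 2:
        return ScenarioSpec(
            name="scenario2",
            invest_frac_restoration=0.01,
            invest_frac_gi=0.01,
            emission_cut=0.55,
            waste_full_treatment=True,
            employment_boost=0.10,
            vehicle_cut=0.25,
            vehicle_emission_cut=0.36,
        )
    raise ValueError(f"no preset scenario {n!r}; choose 0, 1 or 2")


def apply(spec: ScenarioSpec, params: ParameterSet) -> ParameterSet:
    """Fold the scenario levers into a derived, numerically-equivalent
    parameter set (original untouched).

    Employment boost multiplies the base employment rate, the waste lever
    forces the treatment rate to 1, and the emission cuts scale the emission
    factors and the vehicle fleet. Applying ``preset(0)`` is the identity.
    """
    pop = dataclasses.replace(
        params.population,
        employment_rate_base=params.population.employment_rate_base
        * (1.0 + spec.employment_boost),
    )
    pol = dataclasses.replace(
        params.pollution,
        emis_per_capita=params.pollution.emis_per_capita * (1.0 - spec.emission_cut),
        emis_per_vehicle=params.pollution.emis_per_vehicle
        * (1.0 - spec.vehicle_emission_cut),
        vehicles_per_capita=params.pollution.vehicles_per_capita
        * (1.0 - spec.vehicle_cut),
        treatment_rate=1.0 if spec.waste_full_treatment else params.pollution.treatment_rate,
    )
    return params.replace(population=pop, pollution=pol)
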