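"""Parameter containers for the Santander Bay system-dynamics model.

All rates are expressed per year and converted to monthly flows by division
by 12 at the point of use (simple, non-compounding convention). Monetary
constants are EUR; areas are hectares; pollution stocks are tonnes CO2e
(air) and tonnes (waste).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml


@dataclass
class PopulationParams:
    """Demographic subsystem constants (config namespace ``population.*``)."""

    birth_rate: float = 0.0072            # /person/yr
    base_death_rate: float = 0.0096       # /person/yr, before morbidity inflation
    sedentary_base: float = 0.44          # sedentary share with no natural space
    sedentary_max_reduction: float = 0.5  # greenery can halve the sedentary share
    sedentary_diag_share: float = 0.20    # hospital diagnoses tied to sedentarism
    base_morbidity_incidence: float = 0.10  # /person/yr hospital morbidity
    pollution_disease_coeff: float = 0.001  # /yr per unit of pollution index
    morbidity_death_coeff: float = 1.5    # death-rate inflation per unit morbidity
    poverty_coeff: float = 0.5            # poverty rate per unit (1 - employment)
    migration_coeff: float = 0.004        # /yr net out-migration per unit poverty
    employment_rate_base: float = 0.62    # employment rate at reference conditions
    employment_sedentary_sensitivity: float = 0.5  # employment loss per relative
    # increase of the sedentary share over its reference value


@dataclass
class PollutionParams:
    """Air-emissions balance and waste chain (config namespace ``pollution.*``)."""

    emis_per_capita: float = 2.5      # t CO2e/person/yr (non-traffic sources)
    emis_per_vehicle: float = 2.0     # t CO2e/vehicle/yr
    vehicles_per_capita: float = 0.5  # vehicles/person
    absorption_per_ha: float = 20.0   # t CO2e/ha/yr sequestered by eco + GI area
    waste_per_capita: float = 535.1   # kg/person/yr
    treatment_rate: float = 0.80      # fraction of generated waste treated
    waste_decay_rate: float = 0.0     # /yr environmental assimilation of dumped waste
    index_weight_air: float = 1.0     # pollution-index weight of the air stock
    index_weight_waste: float = 1.0   # pollution-index weight of the waste stock


@dataclass
class LandParams:
    """Surface-distribution subsystem constants (config namespace ``land.*``).

    ``land_total`` is the dynamic (non-water) study area in hectares. The
    study area's absolute size is a config input: absolute hectares and EUR
    scale with it, but every share, ratio and ordering result is invariant.
    """

    land_total: float = 22_000.0
    # Initial shares of the four stocks over the dynamic area; ``None`` means
    # "use the CORINE-derived defaults" (see land_area.default_initial_shares).
    share_eco: float | None = None
    share_gi: float | None = None
    share_imp: float | None = None
    share_free: float | None = None
    degradation_rate0: float = 0.0006  # /yr per unit pollution index
    imperm_rate0: float = 0.2          # /yr of uncommitted free area, at P = P0
    restoration_cost: float = 2.0e6    # EUR/ha (acquisition + restoration works)
    gi_cost: float = 3.0e5             # EUR/ha (de-sealing + green build-out)
    erodible_fraction: float = 0.9191  # share of ecosystem area prone to erosion
    gi_target_ha: float = 2_500.0      # planning cap on total GI area
    imp_floor_frac: float = 0.5        # de-sealing floor, fraction of initial imp
    eco_subtype_shares: dict[str, float] = field(
        default_factory=lambda: {
            "Forests and Heathland": 0.12 / 11.21,
            "Croplands": 10.8 / 11.21,
            "Coastal ecosystems": 0.10 / 11.21,
            "Inland waters, wetlands and estuaries": 0.11 / 11.21,
            "Grasslands and Pastures": 0.08 / 11.21,
        }
    )
    gi_subtype_shares: dict[str, float] = field(
        default_factory=lambda: {
            "Green Urban Areas": 0.70,
            "SUDS": 0.10,
            "Urban Gardens": 0.10,
            "Green Corridors": 0.10,
        }
    )


@dataclass
class EconomyParams:
    """Economic subsystem constants (config namespace ``economy.*``)."""

    gdp_per_capita0: float = 15_717.44   # EUR/person/yr
    housing_exp0: float = 3_829.54       # EUR/person/yr housing, energy, water
    food_exp0: float = 1_785.44          # EUR/person/yr food
    housing_variable_share: float = 0.10  # share of housing cost tied to ES
    food_savings_cap: float = 0.20        # max relative food saving from local ES
    employment_elasticity: float = 1.0    # GDP-per-capita elasticity to employment
    noise_barrier_coeff: float = 0.5      # max noise attenuation by green barriers
    heat_regulation_coeff: float = 0.5    # max heat-island damping by greenery


@dataclass
class InitialConditions:
    """Year-2000 stock values (config section ``initial``)."""

    population0: float = 172_000.0     # persons
    air_pollution0: float = 2.0e6      # t CO2e accumulated excess stock
    waste_pollution0: float = 5.0e4    # t dumped-waste stock


@dataclass
class ParameterSet:
    """Every rate and constant of the model, grouped by subsystem."""

    population: PopulationParams = field(default_factory=PopulationParams)
    pollution: PollutionParams = field(default_factory=PollutionParams)
    land: LandParams = field(default_factory=LandParams)
    economy: EconomyParams = field(default_factory=EconomyParams)
    initial: InitialConditions = field(default_factory=InitialConditions)

    def replace(self, **groups: Any) -> "ParameterSet":
        """Return a copy with whole subsystem groups swapped out."""
        return dataclasses.replace(self, **groups)

    def to_dict(self) -> dict[str, Any]:
        return {
            "population": dataclasses.asdict(self.population),
            "pollution": dataclasses.asdict(self.pollution),
            "land": dataclasses.asdict(self.land),
            "economy": dataclasses.asdict(self.economy),
            "initial": dataclasses.asdict(self.initial),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        def build(klass, key):
            return klass(**d.get(key, {}))

        return cls(
            population=build(PopulationParams, "population"),
            pollution=build(PollutionParams, "pollution"),
            land=build(LandParams, "land"),
            economy=build(EconomyParams, "economy"),
            initial=build(InitialConditions, "initial"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_parameters() -> ParameterSet:
    """The shipped calibration: every constant the source statistics print
    (waste 535.1 kg, 80% treatment, 44% sedentary, 20% diagnoses, 91.91%
    erodible, EUR 15,717.44 / 3,829.54 / 1,785.44) plus the package's own
    defaults for the quantities those statistics do not pin down."""
    return ParameterSet()
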