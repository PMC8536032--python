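"""Full-model assembly: stocks, flows and auxiliaries of the Santander run.

Seven level variables are integrated: population, the air-pollution and
waste-pollution stocks, and the four land-surface stocks. Two bookkeeping
cells ride along outside the conservation group: ``cum_restored`` (feeds the
erosion-prevention effect) and ``gdp_lagged`` (the previous year's adjusted
GDP, refreshed every January, funding the investment budgets).

Auxiliaries are pure functions of the stocks at the current step; there is
no intra-step feedback.
"""

from __future__ import annotations

import pandas as pd

from . import economy, land_area, pollution as pol, population as pop
from .ecoservices import (
    SERVICES,
    ValuationTable,
    default_table,
    monthly_es_value,
    subtype_areas,
)
from .engine import EXTERNAL, FlowSpec, SimClock, SimState, run
from .params import ParameterSet, default_parameters
from .scenarios import ScenarioSpec, preset

LAND_STOCKS = ("area_eco", "area_gi", "area_imp", "area_free")

_ES_SLUGS = {
    "Food": "es_food",
    "Materials": "es_materials",
    "Extreme events": "es_extreme_events",
    "Air quality": "es_air_quality",
    "Water purification": "es_water_purification",
    "Climate regulation": "es_climate_regulation",
    "Hydrological cycle management": "es_hydrological",
    "BioControl": "es_biocontrol",
    "Pollination": "es_pollination",
    "Recreational use": "es_recreation",
}

_REGULATION_SERVICES = (
    "Climate regulation",
    "Water purification",
    "Hydrological cycle management",
)


def _half_index(value: float, reference: float) -> float:
    """Map a quantity to [0, 1] relative to its year-2000 reference: total
    loss -> 0, the initial value -> 0.5, a doubling (or more) -> 1."""
    if reference <= 0:
        return 0.0
    rel = (value - reference) / reference
    return min(1.0, max(-1.0, rel)) / 2.0 + 0.5


class SantanderModel:
    """The assembled model for one (parameter set, scenario) pair."""

    def __init__(
        self,
        params: ParameterSet | None = None,
        scenario: ScenarioSpec | None = None,
        table: ValuationTable | None = None,
    ) -> None:
        self.params = params or default_parameters()
        self.scenario = scenario or preset(0)
        self.table = table or default_table()

        areas0 = land_area.initial_areas(self.params.land)
        self._areas0 = areas0
        cls_areas0 = subtype_areas(
            areas0["area_eco"],
            areas0["area_gi"],
            self.params.land.eco_subtype_shares,
            self.params.land.gi_subtype_shares,
        )
        per0, _ = monthly_es_value(cls_areas0, self.table)
        self._reg0 = sum(per0[s] for s in _REGULATION_SERVICES)
        self._food0 = per0["Food"]
        self._veh0 = (
            self.params.pollution.vehicles_per_capita
            * self.params.initial.population0
        )
        k_h = self.params.economy.heat_regulation_coeff
        k_n = self.params.economy.noise_barrier_coeff
        self._heat_norm = 1.0 - k_h * 0.5  # availability is 0.5 at t0
        self._noise_norm = 1.0 - k_n * 0.5

    # ------------------------------------------------------------------ aux
    def auxiliaries(
        self, state: SimState, params: ParameterSet, scenario: ScenarioSpec
    ) -> dict[str, float]:
        p = params
        idx = pol.pollution_index(
            state.air_pollution, state.waste_pollution, p.pollution, p.initial
        )
        avail = land_area.nature_availability(
            state.area_eco, state.area_gi, p.land
        )
        sed = pop.sedentary_fraction(avail, p.population)
        sed_rate, pol_rate = pop.disease_rates(avail, idx, p.population)
        morbidity = sed_rate + pol_rate
        employment = pop.employment_rate(
            sed, p.population, boost=scenario.employment_boost
        )
        poverty = pop.poverty_rate(employment, p.population)
        gdp_pc = economy.gdp_per_capita_update(
            employment, p.population.employment_rate_base, p.economy
        )

        cls_areas = subtype_areas(
            state.area_eco,
            state.area_gi,
            p.land.eco_subtype_shares,
            p.land.gi_subtype_shares,
        )
        per_service, es_total = monthly_es_value(cls_areas, self.table)
        es_annual = es_total * 12.0
        adj_gdp = economy.adjusted_gdp(gdp_pc, state.population, es_annual)
        invest_rest, invest_gi = economy.investment_budgets(
            state.stocks["gdp_lagged"], scenario
        )

        reg_index = _half_index(
            sum(per_service[s] for s in _REGULATION_SERVICES), self._reg0
        )
        food_index = _half_index(per_service["Food"], self._food0)
        expenditure = economy.expenditures_per_capita(
            reg_index, food_index, p.economy
        )

        veh = pol.vehicles(state.population, p.pollution, scenario)
        k_n = p.economy.noise_barrier_coeff
        k_h = p.economy.heat_regulation_coeff
        noise = (
            (veh / self._veh0) * (1.0 - k_n * avail) / self._noise_norm
            if self._veh0 > 0
            else 0.0
        )
        heat = (
            (state.area_imp / self._areas0["area_imp"])
            * (1.0 - k_h * avail)
            / self._heat_norm
        )

        aux: dict[str, float] = {
            "pollution_index": idx,
            "nature_availability": avail,
            "sedentary_fraction": sed,
            "sed_disease_rate": sed_rate,
            "pol_disease_rate": pol_rate,
            "morbidity_rate": morbidity,
            "employment_rate": employment,
            "poverty_rate": poverty,
            "gdp_per_capita": gdp_pc,
            "es_total_month": es_total,
            "es_annual": es_annual,
            "adjusted_gdp": adj_gdp,
            "invest_restoration": invest_rest,
            "invest_gi": invest_gi,
            "expenditure_per_capita": expenditure,
            "sick_population": morbidity * state.population,
            "recreation_value": per_service["Recreational use"],
            "vehicles": veh,
            "noise_rate": noise,
            "heat_island_index": heat,
        }
        for name in SERVICES:
            aux[_ES_SLUGS[name]] = per_service[name]
        return aux

    # ---------------------------------------------------------------- flows
    def flows(self, dt: float = 1.0) -> list[FlowSpec]:
        def births(s, p, sc):
            return pop.births_flow(s.population, p.population)

        def deaths(s, p, sc):
            return pop.deaths_flow(
                s.population, s.aux["morbidity_rate"], p.population
            )

        def emigration(s, p, sc):
            return -pop.migration_flow(
                s.population, s.aux["employment_rate"], p.population
            )

        def emissions(s, p, sc):
            return pol.emissions_inflow(s.population, p.pollution, sc)

        def absorption(s, p, sc):
            return pol.absorption_outflow(
                s.air_pollution, s.area_eco, s.area_gi, p.pollution, dt
            )

        def dumping(s, p, sc):
            return pol.waste_flows(s.population, p.pollution, sc).dumped

        def waste_decay(s, p, sc):
            return p.pollution.waste_decay_rate * s.waste_pollution / 12.0

        def degradation(s, p, sc):
            return land_area.degradation_flow(
                s.area_eco,
                s.aux["pollution_index"],
                s.stocks["cum_restored"],
                p.land,
            )

        def impermeabilization(s, p, sc):
            return land_area.impermeabilization_flow(
                s.area_free,
                s.population,
                s.aux["invest_restoration"],
                p.land,
                p.initial,
                dt,
            )

        def restoration(s, p, sc):
            return land_area.restoration_flow(
                s.area_free, s.aux["invest_restoration"], p.land, dt
            )

        def gi_from_imp(s, p, sc):
            return land_area.gi_build_flows(
                s.area_gi,
                s.area_imp,
                s.area_free,
                s.aux["invest_gi"],
                s.aux["invest_restoration"],
                p.land,
                dt,
            )[0]

        def gi_from_free(s, p, sc):
            return land_area.gi_build_flows(
                s.area_gi,
                s.area_imp,
                s.area_free,
                s.aux["invest_gi"],
                s.aux["invest_restoration"],
                p.land,
                dt,
            )[1]

        return [
            FlowSpec("births", EXTERNAL, "population", births),
            FlowSpec("deaths", "population", EXTERNAL, deaths),
            FlowSpec("emigration", "population", EXTERNAL, emigration),
            FlowSpec("emissions", EXTERNAL, "air_pollution", emissions),
            FlowSpec("absorption", "air_pollution", EXTERNAL, absorption),
            FlowSpec("waste_dumping", EXTERNAL, "waste_pollution", dumping),
            FlowSpec("waste_decay", "waste_pollution", EXTERNAL, waste_decay),
            FlowSpec("degradation", "area_eco", "area_free", degradation),
            FlowSpec(
                "impermeabilization", "area_free", "area_imp", impermeabilization
            ),
            FlowSpec("restoration", "area_free", "area_eco", restoration),
            FlowSpec("gi_from_imp", "area_imp", "area_gi", gi_from_imp),
            FlowSpec("gi_from_free", "area_free", "area_gi", gi_from_free),
        ]

    # ------------------------------------------------------------ post-step
    def post_step(self, old: SimState, new: SimState, eff, dt: float) -> None:
        new.stocks["cum_restored"] += eff["restoration"] * dt
        if (new.t * dt) % 12 == 0:  # January: refresh the budget base
            aux = self.auxiliaries(new, self.params, self.scenario)
            new.stocks["gdp_lagged"] = aux["adjusted_gdp"]

    # -------------------------------------------------------------- running
    def initial_state(self) -> SimState:
        stocks = {
            "population": self.params.initial.population0,
            "air_pollution": self.params.initial.air_pollution0,
            "waste_pollution": self.params.initial.waste_pollution0,
            **self._areas0,
            "cum_restored": 0.0,
            "gdp_lagged": 0.0,
        }
        state = SimState(t=0, stocks=stocks)
        aux = self.auxiliaries(state, self.params, self.scenario)
        state.stocks["gdp_lagged"] = aux["adjusted_gdp"]
        state.aux = self.auxiliaries(state, self.params, self.scenario)
        return state

    def run(self, clock: SimClock | None = None) -> pd.DataFrame:
        clock = clock or SimClock()
        return run(
            self.initial_state(),
            self.params,
            self.scenario,
            self.flows(clock.dt),
            clock,
            aux_fn=self.auxiliaries,
            post_step=self.post_step,
            conserved_groups=[LAND_STOCKS],
        )


def simulate(
    params: ParameterSet | None = None,
    scenario: ScenarioSpec | int = 0,
    clock: SimClock | None = None,
    table: ValuationTable | None = None,
) -> pd.DataFrame:
    """Run one scenario and return its monthly trajectory.

    ``scenario`` may be a ScenarioSpec or a preset number (0, 1 or 2).
    Deterministic given its inputs.
    """
    if isinstance(scenario, int):
        scenario = preset(scenario)
    return SantanderModel(params, scenario, table).run(clock)
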