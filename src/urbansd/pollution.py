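"""Pollution subsystem: air-emissions balance and waste chain.

A single CO2e stock aggregates all airborne pollutant species. Emissions
split into a per-capita and a per-vehicle term so transport policies can act
on them separately; absorption is proportional to the ecosystem plus
green-infrastructure area and can never drive the stock negative. Waste is
generated per capita, a treatment-rate share goes to managed treatment and
the remainder is dumped into the waste-pollution stock.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import InitialConditions, PollutionParams
from .scenarios import ScenarioSpec


def vehicles(population: float, params: PollutionParams, scenario: ScenarioSpec) -> float:
    """Vehicle fleet, derived from population net of the fleet-cut lever."""
    return params.vehicles_per_capita * population * (1.0 - scenario.vehicle_cut)


def emissions_inflow(
    population: float, params: PollutionParams, scenario: ScenarioSpec
) -> float:
    """Gross emissions, t CO2e/month, per-capita and per-vehicle terms with
    the scenario's emission cuts applied."""
    if population < 0:
        raise ValueError("population must be non-negative")
    per_capita = (
        params.emis_per_capita * population * (1.0 - scenario.emission_cut)
    )
    per_vehicle = params.emis_per_vehicle * vehicles(population, params, scenario) * (
        1.0 - scenario.vehicle_emission_cut
    )
    return (per_capita + per_vehicle) / 12.0


def absorption_outflow(
    air_stock: float,
    area_eco: float,
    area_gi: float,
    params: PollutionParams,
    dt: float = 1.0,
) -> float:
    """Absorption by ecosystems and GI, t CO2e/month, linear in green area
    and capped so the stock is drained exactly to zero at most."""
    capacity = params.absorption_per_ha * (area_eco + area_gi) / 12.0
    return min(air_stock / dt, capacity)


class WasteFlows(NamedTuple):
    generated: float  # t/month
    treated: float    # t/month
    dumped: float     # t/month


def waste_flows(
    population: float, params: PollutionParams, scenario: ScenarioSpec
) -> WasteFlows:
    """Monthly waste mass balance: generated = treated + dumped exactly.

    Generation converts the per-capita kg/yr figure to tonnes/month. Under
    the full-treatment lever the effective treatment rate is 1 and dumping
    vanishes regardless of population.
    """
    generated = params.waste_per_capita * population / 12.0 / 1000.0
    eff = 1.0 if scenario.waste_full_treatment else params.treatment_rate
    treated = generated * eff
    return WasteFlows(generated, treated, generated - treated)


def pollution_index(
    air_stock: float,
    waste_stock: float,
    params: PollutionParams,
    initial: InitialConditions,
) -> float:
    """Dimensionless pollution index used by the disease and degradation
    couplings: each stock normalised by its year-2000 value, weighted and
    summed (equals 2 at the initial state with unit weights)."""
    idx = 0.0
    if initial.air_pollution0 > 0:
        idx += params.index_weight_air * air_stock / initial.air_pollution0
    if initial.waste_pollution0 > 0:
        idx += params.index_weight_waste * waste_stock / initial.waste_pollution0
    return idx
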