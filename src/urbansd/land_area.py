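"""Surface-distribution subsystem: four interconverting land stocks.

Ecosystems, green/blue infrastructure (GI), impervious and free surface
partition the dynamic (non-water) study area; every transformation moves
area between two of the stocks so their sum is conserved. Degradation
(ecosystems -> free) scales with the pollution index and the erodible share;
sealing (free -> impervious) scales with population; restoration
(free -> ecosystems) and GI build-out (impervious -> GI, then free -> GI)
are budget-driven. Land committed to the month's restoration demand is not
available for sealing or GI conversion — restoration has priority on the
free-surface donor.
"""

from __future__ import annotations

from .params import InitialConditions, LandParams
from .scenarios import ScenarioSpec

#: CORINE-derived shares of the *total* study area, in percentage points.
POINT_SHARES = {
    "water": 85.65,
    "eco": 10.8 + 0.41,    # agricultural + natural/semi-natural
    "gi": 0.09,            # urban green areas
    "imp": 3.05 - 0.09,    # artificialized net of urban green
    "free": 14.35 - (10.8 + 0.41) - 0.09 - (3.05 - 0.09),
}

#: share of the study area that is dynamic land (water excluded), in points
DYNAMIC_POINTS = 100.0 - POINT_SHARES["water"]


def default_initial_shares() -> dict[str, float]:
    """Initial shares of the four stocks as fractions of the dynamic land.

    Derived from the CORINE 2018 class shares of the study area: water
    bodies (85.65%) are excluded; ecosystems aggregate agricultural plus
    natural/semi-natural land, GI is the urban green areas class, the
    impervious stock is the artificialized area net of urban green, and the
    free surface is the remainder.
    """
    return {k: POINT_SHARES[k] / DYNAMIC_POINTS for k in ("eco", "gi", "imp", "free")}


def green_share_of_artificialized() -> float:
    """Urban green share of the artificialized area, percent (0.09 / 3.05)."""
    return POINT_SHARES["gi"] / 3.05 * 100.0


def initial_areas(params: LandParams) -> dict[str, float]:
    """Initial stock areas in hectares, from configured or default shares."""
    shares = default_initial_shares()
    override = {
        "eco": params.share_eco,
        "gi": params.share_gi,
        "imp": params.share_imp,
        "free": params.share_free,
    }
    out = {}
    for key, frac in shares.items():
        if override[key] is not None:
            frac = override[key]
        out[f"area_{key}"] = frac * params.land_total
    return out


def erodible_effective(cum_restored: float, params: LandParams) -> float:
    """Erodible share of ecosystems, reduced by the erosion-prevention effect
    of cumulative restoration (proportional to the restored share of the
    initial ecosystem area)."""
    area_eco0 = default_initial_shares()["eco"] * params.land_total
    prevention = min(1.0, max(0.0, cum_restored / area_eco0))
    return params.erodible_fraction * (1.0 - prevention)


def degradation_flow(
    area_eco: float,
    pollution_index: float,
    cum_restored: float,
    params: LandParams,
) -> float:
    """Ecosystem degradation, ha/month (ecosystems -> free), proportional to
    the pollution index and the effective erodible share."""
    return (
        params.degradation_rate0
        * pollution_index
        * erodible_effective(cum_restored, params)
        * area_eco
        / 12.0
    )


def restoration_demand(invest_restoration: float, params: LandParams) -> float:
    """Restoration conversion demand, ha/month, from the monthly budget."""
    return invest_restoration / params.restoration_cost


def restoration_flow(
    area_free: float,
    invest_restoration: float,
    params: LandParams,
    dt: float = 1.0,
) -> float:
    """Restoration, ha/month (free -> ecosystems): monthly budget divided by
    the per-hectare restoration cost, capped at the available free area
    (further inflow-aware clamping happens in the engine)."""
    demand = restoration_demand(invest_restoration, params)
    return min(demand, area_free / dt)


def unreserved_free(
    area_free: float, invest_restoration: float, params: LandParams, dt: float = 1.0
) -> float:
    """Free area not committed to the month's restoration demand."""
    return max(0.0, area_free - restoration_demand(invest_restoration, params) * dt)


def impermeabilization_flow(
    area_free: float,
    population: float,
    invest_restoration: float,
    params: LandParams,
    initial: InitialConditions,
    dt: float = 1.0,
) -> float:
    """Sealing, ha/month (free -> impervious), proportional to population
    relative to its year-2000 value and to the uncommitted free area."""
    if initial.population0 <= 0:
        return 0.0
    free = unreserved_free(area_free, invest_restoration, params, dt)
    return (
        params.imperm_rate0 * (population / initial.population0) * free / 12.0
    )


def gi_build_flows(
    area_gi: float,
    area_imp: float,
    area_free: float,
    invest_gi: float,
    invest_restoration: float,
    params: LandParams,
    dt: float = 1.0,
) -> tuple[float, float]:
    """GI build-out, ha/month, as (impervious -> GI, free -> GI).

    The budget converts impervious surface first (de-sealing) down to the
    configured impervious floor; once the floor is reached the remaining
    budget draws on the uncommitted free surface. Total GI is capped at the
    planning target ``gi_target_ha``.
    """
    budget_rate = invest_gi / params.gi_cost
    headroom = max(0.0, params.gi_target_ha - area_gi) / dt
    budget_rate = min(budget_rate, headroom)

    floor = params.imp_floor_frac * (
        default_initial_shares()["imp"] * params.land_total
    )
    from_imp = min(budget_rate, max(0.0, area_imp - floor) / dt)
    free_avail = unreserved_free(area_free, invest_restoration, params, dt) / dt
    from_free = min(budget_rate - from_imp, free_avail)
    return from_imp, from_free


def nature_availability(
    area_eco: float, area_gi: float, params: LandParams
) -> float:
    """Availability of natural space, an index in [0, 1].

    The combined ecosystem + GI area is compared with its year-2000 value:
    total loss maps to 0, the initial state to 0.5 and a doubling (or more)
    to 1, linearly in between.
    """
    shares = default_initial_shares()
    a0 = (shares["eco"] + shares["gi"]) * params.land_total
    rel = (area_eco + area_gi - a0) / a0
    return min(1.0, max(-1.0, rel)) / 2.0 + 0.5
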