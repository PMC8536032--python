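"""Economic subsystem: adjusted GDP, employment link, expenditures, budgets.

The welfare indicator is

    adjusted GDP = GDP per capita x population + annual ecosystem services,

i.e. market output plus the monetised flow of ecosystem services. GDP per
capita moves with the employment rate (unit elasticity by default).
Household expenditure per capita is a quality-of-life indicator only — the
savings that ecosystem services generate are NOT subtracted from adjusted
GDP, which already counts the services once. Investment budgets are funded
as fixed fractions of the previous year's adjusted GDP (lagged to avoid
intra-step simultaneity).
"""

from __future__ import annotations

from .params import EconomyParams
from .scenarios import ScenarioSpec


def adjusted_gdp(gdp_per_capita: float, population: float, es_annual: float) -> float:
    """Adjusted GDP, EUR/yr: gdp_per_capita x population + es_annual."""
    if gdp_per_capita < 0 or population < 0 or es_annual < 0:
        raise ValueError("adjusted GDP inputs must be non-negative")
    return gdp_per_capita * population + es_annual


def gdp_per_capita_update(
    employment_rate: float, employment_rate_base: float, params: EconomyParams
) -> float:
    """GDP per capita, EUR/person/yr, scaling with employment relative to
    its base rate with elasticity ``employment_elasticity`` (default 1)."""
    if employment_rate_base <= 0:
        raise ValueError("base employment rate must be positive")
    return params.gdp_per_capita0 * (
        employment_rate / employment_rate_base
    ) ** params.employment_elasticity


def expenditures_per_capita(
    regulation_index: float, food_index: float, params: EconomyParams
) -> float:
    """Household expenditure per capita, EUR/person/yr (indicator only).

    The variable share (10%) of housing/energy/water expenditure falls
    linearly with the joint climate-regulation / water-purification /
    hydrological-cycle service index ``regulation_index`` in [0, 1]; food
    expenditure falls with the food-provision index up to the savings cap.
    """
    for name, idx in (("regulation", regulation_index), ("food", food_index)):
        if not 0.0 <= idx <= 1.0:
            raise ValueError(f"{name} index must lie in [0, 1], got {idx}")
    housing = params.housing_exp0 * (
        (1.0 - params.housing_variable_share)
        + params.housing_variable_share * (1.0 - regulation_index)
    )
    food = params.food_exp0 * (1.0 - params.food_savings_cap * food_index)
    return housing + food


def investment_budgets(
    adjusted_gdp_prev: float, scenario: ScenarioSpec
) -> tuple[float, float]:
    """(restoration, GI) budgets, EUR/month, as scenario fractions of the
    previous year's adjusted GDP. Zero-investment scenarios yield (0, 0)."""
    if adjusted_gdp_prev < 0:
        raise ValueError("lagged adjusted GDP must be non-negative")
    return (
        scenario.invest_frac_restoration * adjusted_gdp_prev / 12.0,
        scenario.invest_frac_gi * adjusted_gdp_prev / 12.0,
    )
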