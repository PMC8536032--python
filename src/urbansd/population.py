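"""Demographic subsystem: births, deaths via morbidity, migration via poverty.

The population stock is driven by four channels. Births are proportional to
population. Deaths carry the base mortality inflated multiplicatively by the
morbidity rate, itself the sum of a sedentary-lifestyle disease channel
(eased by the availability of natural space) and a pollution-related disease
channel (proportional to the normalised pollution index). Net migration is
out-migration proportional to the risk-of-poverty rate, which moves
inversely with the employment rate.
"""

from __future__ import annotations

from .params import PopulationParams


def sedentary_fraction(nature_availability: float, params: PopulationParams) -> float:
    """Sedentary share of the population given nature availability in [0, 1].

    44% of the population is sedentary with no natural space at all
    (availability 0) and greater availability of ecosystems and green/blue
    infrastructure reduces the share linearly, by up to half at
    availability 1.
    """
    if not 0.0 <= nature_availability <= 1.0:
        raise ValueError(
            f"nature availability must lie in [0, 1], got {nature_availability}"
        )
    return params.sedentary_base * (
        1.0 - params.sedentary_max_reduction * nature_availability
    )


def sedentary_reference(params: PopulationParams) -> float:
    """Sedentary share at the initial (year-2000) availability of 0.5."""
    return sedentary_fraction(0.5, params)


def disease_rates(
    nature_availability: float, pollution_index: float, params: PopulationParams
) -> tuple[float, float]:
    """(sedentary, pollution) disease incidence rates, both /person/yr.

    The sedentary channel is the base hospital-morbidity incidence times the
    share of diagnoses tied to sedentarism, scaled by the current sedentary
    share relative to its no-nature baseline; the pollution channel is
    proportional to the pollution index.
    """
    if pollution_index < 0.0:
        raise ValueError("pollution index must be non-negative")
    sed = sedentary_fraction(nature_availability, params)
    sedentary_rate = (
        params.base_morbidity_incidence
        * params.sedentary_diag_share
        * sed
        / params.sedentary_base
    )
    pollution_rate = params.pollution_disease_coeff * pollution_index
    return sedentary_rate, pollution_rate


def morbidity_rate(
    nature_availability: float, pollution_index: float, params: PopulationParams
) -> float:
    """Total morbidity incidence (/person/yr): sum of the two channels."""
    sed, pol = disease_rates(nature_availability, pollution_index, params)
    return sed + pol


def employment_rate(
    sedentary: float, params: PopulationParams, boost: float = 0.0
) -> float:
    """Employment rate; falls as the sedentary share rises above its
    year-2000 reference, and is lifted multiplicatively by employment
    policies. Clipped to (0, 1]."""
    ref = sedentary_reference(params)
    rate = (
        params.employment_rate_base
        * (1.0 + boost)
        * (1.0 - params.employment_sedentary_sensitivity * (sedentary - ref) / ref)
    )
    return min(1.0, max(1e-6, rate))


def poverty_rate(employment: float, params: PopulationParams) -> float:
    """Risk-of-poverty rate, inversely proportional to employment."""
    if not 0.0 < employment <= 1.0:
        raise ValueError("employment rate must lie in (0, 1]")
    return params.poverty_coeff * (1.0 - employment)


def births_flow(population: float, params: PopulationParams) -> float:
    """Births, persons/month."""
    return params.birth_rate * population / 12.0


def deaths_flow(
    population: float, morbidity: float, params: PopulationParams
) -> float:
    """Deaths, persons/month; base mortality inflated by morbidity."""
    rate = params.base_death_rate * (
        1.0 + params.morbidity_death_coeff * morbidity
    )
    return rate * population / 12.0


def migration_flow(
    population: float, employment: float, params: PopulationParams
) -> float:
    """Net migration, persons/month (negative = out-migration).

    Out-migration grows with the risk-of-poverty rate; full employment
    yields zero net migration.
    """
    pov = poverty_rate(employment, params)
    return -params.migration_coeff * pov * population / 12.0
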