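"""Assembled model: determinism, structure and cross-scenario behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import urbansd
from urbansd.model import LAND_STOCKS, simulate


def test_identical_inputs_give_bitwise_identical_trajectories():
    clock = urbansd.SimClock(2000, 2005)
    a = simulate(scenario=0, clock=clock)
    b = simulate(scenario=0, clock=clock)
    pd.testing.assert_frame_equal(a, b)


def test_full_run_row_count_and_columns(scenario_runs):
    df = scenario_runs[0]
    assert len(df) == 601
    for col in (
        "population",
        "air_pollution",
        "waste_pollution",
        *LAND_STOCKS,
        "adjusted_gdp",
        "morbidity_rate",
        "heat_island_index",
        "es_total_month",
    ):
        assert col in df.columns


def test_land_total_conserved_every_month(scenario_runs):
    for df in scenario_runs.values():
        total = df[list(LAND_STOCKS)].sum(axis=1)
        assert np.all(
            np.abs(total - total.iloc[0]) <= 1e-9 * total.iloc[0]
        )


def test_all_stocks_stay_non_negative(scenario_runs):
    stocks = ["population", "air_pollution", "waste_pollution", *LAND_STOCKS]
    for df in scenario_runs.values():
        assert (df[stocks] >= 0).all().all()


def test_population_decreasing_through_2039(scenario_runs):
    pop = scenario_runs[0].loc[scenario_runs[0]["year"] <= 2039, "population"]
    assert np.all(np.diff(pop.to_numpy()) < 0)


def test_population_stays_non_negative_across_a_parameter_grid():
    base = urbansd.default_parameters()
    clock = urbansd.SimClock(2000, 2010)
    for birth in (0.0, 0.02):
        for death in (0.0, 0.03):
            for migration in (0.0, 0.05):
                pop = dataclasses.replace(
                    base.population,
                    birth_rate=birth,
                    base_death_rate=death,
                    migration_coeff=migration,
                )
                df = simulate(base.replace(population=pop), 0, clock)
                assert (df["population"] >= 0).all()


def test_scenario2_morbidity_below_scenario0_at_2050(scenario_runs):
    assert (
        scenario_runs[2]["morbidity_rate"].iloc[-1]
        <= scenario_runs[0]["morbidity_rate"].iloc[-1]
    )


def test_recreation_service_higher_under_the_policy_scenario(scenario_runs):
    assert (
        scenario_runs[2]["recreation_value"].iloc[-1]
        > scenario_runs[0]["recreation_value"].iloc[-1]
    )


def test_degradation_rate_lower_under_the_policy_scenario_at_2050(scenario_runs):
    assert (
        scenario_runs[2]["flow_degradation"].iloc[-1]
        < scenario_runs[0]["flow_degradation"].iloc[-1]
    )


def test_quality_of_life_indicators_ordered_at_2050(scenario_runs):
    last = {n: df.iloc[-1] for n, df in scenario_runs.items()}
    assert last[2]["poverty_rate"] < last[0]["poverty_rate"]
    assert last[2]["expenditure_per_capita"] < last[0]["expenditure_per_capita"]
    assert last[2]["noise_rate"] < last[0]["noise_rate"]
    assert last[2]["sick_population"] < last[0]["sick_population"]


def test_gi_area_non_decreasing_under_investment(scenario_runs):
    gi = scenario_runs[1]["area_gi"].to_numpy()
    assert np.all(np.diff(gi) >= -1e-9)


def test_impervious_surface_shrinks_only_with_gi_investment(scenario_runs):
    assert (
        scenario_runs[2]["area_imp"].iloc[-1]
        < scenario_runs[0]["area_imp"].iloc[-1]
    )
    assert (
        scenario_runs[0]["area_imp"].iloc[-1]
        > scenario_runs[0]["area_imp"].iloc[0]
    )


def test_indicator_indices_normalised_to_one_at_start(scenario_runs):
    first = scenario_runs[0].iloc[0]
    assert first["heat_island_index"] == pytest.approx(1.0)
    assert first["noise_rate"] == pytest.approx(1.0)
    assert first["pollution_index"] == pytest.approx(2.0)
    assert first["nature_availability"] == pytest.approx(0.5)
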