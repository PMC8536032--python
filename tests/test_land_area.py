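"""Land-surface stocks: initial shares, transformation flows, availability."""

import pytest

from urbansd import land_area
from urbansd.params import InitialConditions, LandParams


@pytest.fixture
def params():
    return LandParams()


def test_default_point_shares_sum_to_the_dynamic_area():
    pts = land_area.POINT_SHARES
    assert pts["eco"] + pts["gi"] + pts["imp"] + pts["free"] == pytest.approx(14.35)
    assert pts["water"] == 85.65
    fracs = land_area.default_initial_shares()
    assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)


def test_green_share_of_artificialized_area_is_2_95_percent():
    assert land_area.green_share_of_artificialized() == pytest.approx(2.95, abs=0.005)


def test_initial_areas_scale_with_land_total(params):
    areas = land_area.initial_areas(params)
    assert sum(areas.values()) == pytest.approx(params.land_total)
    double = land_area.initial_areas(LandParams(land_total=44_000.0))
    for k in areas:
        assert double[k] == pytest.approx(2 * areas[k])


def test_degradation_proportional_to_pollution_index(params):
    assert land_area.degradation_flow(1000.0, 0.0, 0.0, params) == 0.0
    one = land_area.degradation_flow(1000.0, 1.0, 0.0, params)
    assert land_area.degradation_flow(1000.0, 2.0, 0.0, params) == pytest.approx(
        2 * one
    )


def test_restoration_reduces_the_effective_erodible_share(params):
    assert land_area.erodible_effective(0.0, params) == pytest.approx(0.9191)
    partial = land_area.erodible_effective(1000.0, params)
    assert 0.0 < partial < 0.9191
    assert land_area.erodible_effective(1e9, params) == 0.0


def test_impermeabilization_scales_with_population(params):
    initial = InitialConditions()
    assert (
        land_area.impermeabilization_flow(100.0, 0.0, 0.0, params, initial) == 0.0
    )
    at_p0 = land_area.impermeabilization_flow(
        100.0, initial.population0, 0.0, params, initial
    )
    assert at_p0 == pytest.approx(params.imperm_rate0 * 100.0 / 12.0)
    # restoration-committed free area is not available for sealing
    committed = land_area.impermeabilization_flow(
        100.0, initial.population0, 50.0 * params.restoration_cost, params, initial
    )
    assert committed == pytest.approx(params.imperm_rate0 * 50.0 / 12.0)


def test_restoration_budget_division_and_cap():
    params = LandParams(restoration_cost=50_000.0)
    assert land_area.restoration_flow(1e6, 1_000_000.0, params) == pytest.approx(20.0)
    assert land_area.restoration_flow(5.0, 1_000_000.0, params) == pytest.approx(5.0)
    assert land_area.restoration_flow(1e6, 0.0, params) == 0.0


def test_gi_build_draws_impervious_first_then_free():
    params = LandParams(gi_cost=100_000.0, gi_target_ha=1e9, imp_floor_frac=0.0)
    from_imp, from_free = land_area.gi_build_flows(
        0.0, 1000.0, 1000.0, 500_000.0, 0.0, params
    )
    assert (from_imp, from_free) == (pytest.approx(5.0), 0.0)
    # impervious at the floor: the budget falls through to the free surface
    from_imp, from_free = land_area.gi_build_flows(
        0.0, 0.0, 1000.0, 500_000.0, 0.0, params
    )
    assert (from_imp, from_free) == (0.0, pytest.approx(5.0))
    assert land_area.gi_build_flows(0.0, 1000.0, 1000.0, 0.0, 0.0, params) == (
        0.0,
        0.0,
    )


def test_gi_build_respects_the_planning_target():
    params = LandParams(gi_cost=100_000.0, gi_target_ha=100.0, imp_floor_frac=0.0)
    from_imp, from_free = land_area.gi_build_flows(
        98.0, 1000.0, 1000.0, 500_000.0, 0.0, params
    )
    assert from_imp + from_free == pytest.approx(2.0)


@pytest.mark.parametrize(
    "factor,expected", [(1.0, 0.5), (0.0, 0.0), (2.0, 1.0), (3.0, 1.0)]
)
def test_nature_availability_midpoint_mapping(params, factor, expected):
    a0 = (
        land_area.default_initial_shares()["eco"]
        + land_area.default_initial_shares()["gi"]
    ) * params.land_total
    assert land_area.nature_availability(a0 * factor, 0.0, params) == pytest.approx(
        expected
    )
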