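"""Stock-and-flow integrator: stepping, clamping, conservation, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from urbansd.engine import (
    EXTERNAL,
    EngineError,
    FlowSpec,
    SimClock,
    SimState,
    run,
    step,
)


def const_flow(name, source, sink, rate):
    return FlowSpec(name, source, sink, lambda s, p, sc: rate)


def test_clock_step_count_and_validation():
    assert SimClock(2000, 2050, 1.0).n_steps == 600
    assert SimClock(2000, 2050, 1.0).month_of_year(2010) == 120
    with pytest.raises(ValueError):
        SimClock(2000, 2050, 0.0)
    with pytest.raises(ValueError):
        SimClock(2000, 2001, 7.0)  # not an integer number of steps


def test_single_inflow_adds_to_stock():
    state = SimState(stocks={"population": 170_000.0})
    new = step(state, None, None, [const_flow("births", EXTERNAL, "population", 102.0)])
    assert new.stocks["population"] == pytest.approx(170_102.0)
    assert new.t == 1


def test_zero_rates_leave_state_unchanged_except_time():
    state = SimState(stocks={"a": 5.0, "b": 7.0})
    flows = [const_flow("f", "a", "b", 0.0), const_flow("g", "b", EXTERNAL, 0.0)]
    new = step(state, None, None, flows)
    assert new.stocks == state.stocks
    assert new.t == state.t + 1


def test_outflow_clamped_to_source_and_sink_gains_exactly_the_transfer():
    state = SimState(stocks={"area_free": 4.0, "area_eco": 10.0})
    new = step(state, None, None, [const_flow("f", "area_free", "area_eco", 10.0)])
    assert new.stocks["area_free"] == 0.0
    assert new.stocks["area_eco"] == pytest.approx(14.0)


def test_clamping_accounts_for_concurrent_inflow():
    # the source receives 2/month, so 6 (not 4) can flow out
    state = SimState(stocks={"a": 4.0, "b": 0.0})
    flows = [
        const_flow("in", EXTERNAL, "a", 2.0),
        const_flow("out", "a", "b", 10.0),
    ]
    new = step(state, None, None, flows)
    assert new.stocks["a"] == 0.0
    assert new.stocks["b"] == pytest.approx(6.0)


def test_non_finite_rate_aborts_naming_the_flow():
    state = SimState(stocks={"a": 1.0})
    bad = FlowSpec("diverging", "a", EXTERNAL, lambda s, p, sc: math.nan)
    with pytest.raises(EngineError, match="diverging"):
        step(state, None, None, [bad])


@given(
    stock=st.floats(0.0, 1e6),
    rate_out=st.floats(0.0, 1e5),
    rate_in=st.floats(0.0, 1e5),
)
def test_clamping_never_negative_and_never_creates_mass(stock, rate_out, rate_in):
    state = SimState(stocks={"a": stock, "b": 0.0})
    flows = [
        const_flow("in", EXTERNAL, "a", rate_in),
        const_flow("out", "a", "b", rate_out),
    ]
    new = step(state, None, None, flows)
    assert new.stocks["a"] >= 0.0
    # transferred mass never exceeds what was available
    assert new.stocks["b"] <= stock + rate_in + 1e-6


def proportional_population_flows(rate_per_year):
    return [
        FlowSpec(
            "net_growth",
            EXTERNAL,
            "population",
            lambda s, p, sc: rate_per_year * s.stocks["population"] / 12.0,
        )
    ]


def test_proportional_flow_matches_geometric_closed_form():
    clock = SimClock(2000, 2001, 1.0)
    initial = SimState(stocks={"population": 100_000.0})
    traj = run(initial, None, None, proportional_population_flows(0.012), clock)
    expected = 100_000.0 * (1.0 + 0.012 / 12.0) ** np.arange(13)
    np.testing.assert_allclose(traj["population"].to_numpy(), expected, rtol=1e-12)
    assert traj["population"].iloc[-1] == pytest.approx(101_206.6, abs=0.05)


def test_run_is_deterministic_and_has_n_steps_plus_one_rows():
    clock = SimClock(2000, 2002, 1.0)
    initial = SimState(stocks={"population": 1000.0})
    flows = proportional_population_flows(-0.01)
    a = run(initial, None, None, flows, clock)
    b = run(initial, None, None, flows, clock)
    assert len(a) == clock.n_steps + 1
    assert a.equals(b)


def test_conservation_check_aborts_with_step_index():
    leak = [const_flow("leak", "a", EXTERNAL, 1.0)]
    initial = SimState(stocks={"a": 100.0, "b": 0.0})
    with pytest.raises(EngineError, match="step 1"):
        run(
            initial,
            None,
            None,
            leak,
            SimClock(2000, 2001, 1.0),
            conserved_groups=[("a", "b")],
        )
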