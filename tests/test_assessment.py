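"""Assessment arithmetic: percentage increases, compounding, benefit ratio."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import urbansd
from urbansd import assessment as ass


@pytest.mark.parametrize(
    "b,a,expected",
    [
        (3019.27, 2589.35, 16.60),
        (3551.24, 3503.01, 1.38),
        (100.0, 100.0, 0.00),
    ],
)
def test_percent_increase_matches_reported_rounding(b, a, expected):
    assert ass.percent_increase(b, a) == expected


def test_percent_increase_requires_positive_reference():
    with pytest.raises(ValueError):
        ass.percent_increase(1.0, 0.0)


@pytest.mark.parametrize(
    "ab,bc,expected",
    [(13.24, 16.60, 32.04), (10.08, 10.82, 21.99), (0.0, 5.5, 5.5)],
)
def test_chain_increase_compounds_multiplicatively(ab, bc, expected):
    assert ass.chain_increase(ab, bc) == expected


@pytest.mark.parametrize(
    "gdp,inv,expected",
    [(3503.01, 35.03, 100.00), (2589.35, 25.89, 100.01), (7.0, 7.0, 1.00)],
)
def test_benefit_ratio(gdp, inv, expected):
    assert ass.benefit_ratio(gdp, inv) == expected
    with pytest.raises(ValueError):
        ass.benefit_ratio(1.0, 0.0)


@given(
    g0=st.floats(100.0, 1e5),
    g1=st.floats(100.0, 1e5),
    g2=st.floats(100.0, 1e5),
)
def test_compounding_identity_on_random_gdp_triples(g0, g1, g2):
    r01 = (g1 / g0 - 1.0) * 100.0
    r12 = (g2 / g1 - 1.0) * 100.0
    r02 = (g2 / g0 - 1.0) * 100.0
    assert ass.chain_increase(r01, r12) == pytest.approx(r02, abs=0.011)


def test_half_up_rounding_convention():
    assert ass.round2(1.005) == 1.01
    assert ass.round2(2.675) == 2.68
    assert ass.round2(-1.005) == -1.01  # ties round away from zero


def test_reference_tables_roundtrip_reported_increases():
    """From the reported decade-year investment/GDP figures, the package's
    operations reproduce the reported pairwise-increase table to 0.01 pts."""
    ref = ass.load_reference_tables()
    inv = ref["investment_gdp"].set_index(["scenario", "year"])
    inc = ref["increases"].set_index(["pair", "year"])["increase_pct"]
    for year in ass.DEFAULT_YEARS:
        computed = ass.percent_increase(
            float(inv.loc[(2, year), "gdp_eur_mill"]),
            float(inv.loc[(1, year), "gdp_eur_mill"]),
        )
        assert computed == pytest.approx(
            float(inc.loc[("case1_case2", year)]), abs=0.01
        )
        chained = ass.chain_increase(
            float(inc.loc[("case0_case1", year)]), computed
        )
        assert chained == pytest.approx(
            float(inc.loc[("case0_case2", year)]), abs=0.01
        )


def test_build_report_on_identical_trajectories_gives_zero_increases():
    clock = urbansd.SimClock(2000, 2020)
    df = urbansd.simulate(scenario=1, clock=clock)
    tables = ass.build_report({0: df, 1: df, 2: df}, years=(2010, 2020))
    t5 = tables["table5"]
    assert (t5[["case0_case1", "case0_case2", "case1_case2"]] == 0.0).all().all()
    assert set(tables) == {"table3", "table4", "table5"}


def test_build_report_emits_decade_tables_and_identity(tmp_path, scenario_runs):
    tables = ass.build_report(scenario_runs, out_dir=tmp_path)
    for name in ("table3", "table4", "table5"):
        assert (tmp_path / f"{name}.csv").exists()
    t5 = tables["table5"]
    assert list(t5["year"]) == list(ass.DEFAULT_YEARS)
    # every pairwise increase is positive under investment and policies
    assert (t5[["case0_case1", "case0_case2", "case1_case2"]] > 0).all().all()
    t3 = tables["table3"]
    assert (t3["investment_eur_mill"] > 0).all()


def test_indicator_table_columns(scenario_runs):
    ind = ass.indicators(scenario_runs[0])
    assert set(ass.INDICATOR_COLUMNS) <= set(ind.columns)
    assert len(ind) == len(scenario_runs[0])
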