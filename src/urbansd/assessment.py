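"""Scenario comparison and economic assessment.

Desk-scale arithmetic on adjusted-GDP trajectories or on the study's
reported decade-year tables: pairwise percentage increases, the compounding
identity linking them, and the benefit-to-investment ratio behind the
"EUR 1 invested -> EUR 100 of GDP" headline (total GDP divided by
investment, the reading the reported tables support). Percentages and
ratios are rounded half-up to two decimals, matching the tables'
presentation. A per-month quality-of-life indicator table (poverty,
expenditure, sick population, morbidity, recreation, noise, heat island)
is extracted from any trajectory.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

INDICATOR_COLUMNS = (
    "poverty_rate",
    "expenditure_per_capita",
    "sick_population",
    "morbidity_rate",
    "recreation_value",
    "noise_rate",
    "heat_island_index",
)

DEFAULT_YEARS = (2010, 2020, 2030, 2040, 2050)


def round2(x: float) -> float:
    """Half-up rounding to two decimals (presentation convention)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def percent_increase(value_b: float, value_a: float) -> float:
    """Percentage increase of ``value_b`` over ``value_a``, two decimals."""
    if value_a <= 0:
        raise ValueError("reference value must be positive")
    return round2((value_b / value_a - 1.0) * 100.0)


def chain_increase(pct_ab: float, pct_bc: float) -> float:
    """Compose two percentage increases: ((1+a)(1+b) - 1), two decimals."""
    return round2(((1.0 + pct_ab / 100.0) * (1.0 + pct_bc / 100.0) - 1.0) * 100.0)


def benefit_ratio(gdp: float, investment: float) -> float:
    """GDP over investment (same units), two decimals."""
    if investment <= 0:
        raise ValueError("investment must be positive")
    return round2(gdp / investment)


def indicators(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Per-month quality-of-life indicator table from a trajectory."""
    cols = ["month_index", "date", "year", *INDICATOR_COLUMNS]
    return trajectory[cols].copy()


def _at_years(trajectory: pd.DataFrame, years: Sequence[int]) -> pd.DataFrame:
    jan = trajectory[trajectory["month_index"] % 12 == 0].set_index("year")
    missing = set(years) - set(jan.index)
    if missing:
        raise ValueError(f"trajectory does not cover years {sorted(missing)}")
    return jan.loc[list(years)]


def build_report(
    trajectories: Mapping[int, pd.DataFrame],
    years: Sequence[int] = DEFAULT_YEARS,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Decade-year assessment tables from the three scenario trajectories.

    Emits the investment/GDP table for each investing scenario (table3,
    table4; EUR million) and the pairwise percent-increase table (table5),
    and asserts the compounding identity
    chain(case0-1, case1-2) = case0-2 to 0.01 points.
    """
    for n in (0, 1, 2):
        if n not in trajectories:
            raise ValueError(f"scenario {n} trajectory is required")

    tables: dict[str, pd.DataFrame] = {}
    for name, n in (("table3", 1), ("table4", 2)):
        rows = _at_years(trajectories[n], years)
        tables[name] = pd.DataFrame(
            {
                "year": list(years),
                "investment_eur_mill": [
                    round2((r.invest_restoration + r.invest_gi) * 12.0 / 1e6)
                    for r in rows.itertuples()
                ],
                "gdp_eur_mill": [
                    round2(r.adjusted_gdp / 1e6) for r in rows.itertuples()
                ],
            }
        )

    gdp = {
        n: _at_years(trajectories[n], years)["adjusted_gdp"].to_numpy()
        for n in (0, 1, 2)
    }
    pairs = {
        "case0_case1": (gdp[1], gdp[0]),
        "case0_case2": (gdp[2], gdp[0]),
        "case1_case2": (gdp[2], gdp[1]),
    }
    t5 = pd.DataFrame(
        {
            "year": list(years),
            **{
                pair: [percent_increase(b, a) for b, a in zip(num, den)]
                for pair, (num, den) in pairs.items()
            },
        }
    )
    for i in range(len(years)):
        chained = chain_increase(
            t5["case0_case1"].iloc[i], t5["case1_case2"].iloc[i]
        )
        direct = t5["case0_case2"].iloc[i]
        if abs(chained - direct) > 0.01 + 1e-9:
            raise AssertionError(
                f"compounding identity violated at {years[i]}: "
                f"chain={chained} direct={direct}"
            )
    tables["table5"] = t5

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out_dir / f"{name}.csv", index=False)
    return tables


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Reported decade-year assessment figures for the Santander study
    (EUR million and percent), used as inputs to the desk-scale checks."""
    out = {}
    for key, fname in (
        ("investment_gdp", "reference_investment_gdp.csv"),
        ("increases", "reference_gdp_increases.csv"),
    ):
        path = resources.files("urbansd.data").joinpath(fname)
        with resources.as_file(path) as p:
            out[key] = pd.read_csv(p)
    return out


def reference_assessment() -> dict[str, float]:
    """Recompute the headline assessment arithmetic from the reported
    decade-year tables (inputs), with the package's own operations.

    Returns the key quantities: the Scenario 1 -> 2 adjusted-GDP increases
    at 2010 and 2050, the compounded Scenario 0 -> 2 increases at 2040 and
    2050, and the benefit-to-investment ratios at 2010 and 2050.
    """
    ref = load_reference_tables()
    inv = ref["investment_gdp"].set_index(["scenario", "year"])
    inc = ref["increases"].set_index(["pair", "year"])["increase_pct"]

    def gdp(scen: int, year: int) -> float:
        return float(inv.loc[(scen, year), "gdp_eur_mill"])

    def investment(scen: int, year: int) -> float:
        return float(inv.loc[(scen, year), "investment_eur_mill"])

    case12 = {
        year: percent_increase(gdp(2, year), gdp(1, year))
        for year in DEFAULT_YEARS
    }
    return {
        "case1_case2_2010_pct": case12[2010],
        "case1_case2_2050_pct": case12[2050],
        "case0_case2_2040_pct": chain_increase(
            float(inc.loc[("case0_case1", 2040)]), case12[2040]
        ),
        "case0_case2_2050_pct": chain_increase(
            float(inc.loc[("case0_case1", 2050)]), case12[2050]
        ),
        "benefit_ratio_2010": benefit_ratio(gdp(1, 2010), investment(1, 2010)),
        "benefit_ratio_2050": benefit_ratio(gdp(1, 2050), investment(1, 2050)),
    }
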