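"""Seeded generators for every input fixture the pipeline consumes.

The real study calibrated against regional statistics (population series,
air-emissions accounts, land-cover shares, household-expenditure constants)
that carry no accession identifiers, so this module emulates them: a
demographic series with the decreasing trend the study reports, an
emissions account split into per-capita and per-vehicle parts, the printed
land-cover shares, and the valuation-table fixture. Every generator is pure
given its seed; noise is multiplicative lognormal (mean-preserving), the
natural choice for positive series with roughly proportional errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecoservices import default_table
from .params import ParameterSet, default_parameters


def demographic_series(
    P0: float, birth_rate: float, death_rate: float, n_years: int
) -> pd.DataFrame:
    """Noise-free demographic skeleton over ``n_years`` years.

    Monthly geometric population P_m = P0 (1 + (b - d)/12)^m — exactly what
    explicit monthly stepping of proportional birth/death flows produces.
    Returns year-start population and annual birth/death counts.
    """
    if n_years < 1:
        raise ValueError("need at least one year")
    g = 1.0 + (birth_rate - death_rate) / 12.0
    months = np.arange(12 * n_years)
    P = P0 * g**months
    pop_year = P[::12]
    monthly = P.reshape(n_years, 12).sum(axis=1)
    return pd.DataFrame(
        {
            "year_offset": np.arange(n_years),
            "population": pop_year,
            "births": birth_rate / 12.0 * monthly,
            "deaths": death_rate / 12.0 * monthly,
        }
    )


def _lognoise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.standard_normal(size) * sigma - sigma**2 / 2.0)


def gen_population_series(
    P0: float = 172_000.0,
    birth_rate: float = 0.0072,
    death_rate: float = 0.0096,
    noise_cv: float = 0.01,
    seed: int = 0,
    start_year: int = 2000,
    observed_end: int = 2020,
    projection_end: int = 2039,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual population series split into an observed window (by default
    2000-2020) and a projection window (2021-2039).

    The skeleton is the geometric demographic series (decreasing trend at
    the default net rate) with seeded multiplicative lognormal noise of
    coefficient ``noise_cv`` applied to every column.
    """
    n_years = projection_end - start_year + 1
    df = demographic_series(P0, birth_rate, death_rate, n_years)
    df["year"] = start_year + df.pop("year_offset")
    rng = np.random.default_rng(seed)
    for col in ("population", "births", "deaths"):
        df[col] = df[col] * _lognoise(rng, noise_cv, len(df))
    df = df[["year", "population", "births", "deaths"]]
    observed = df[df["year"] <= observed_end].reset_index(drop=True)
    projection = df[df["year"] > observed_end][["year", "population"]].reset_index(
        drop=True
    )
    return observed, projection


def gen_emissions_series(
    population: pd.DataFrame,
    params: ParameterSet | None = None,
    noise_cv: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Annual emissions account (t CO2e): per-capita part + vehicle part.

    ``population`` must carry (year, population) columns; with zero noise
    the totals reproduce the two-term emission formula exactly.
    """
    params = params or default_parameters()
    p = params.pollution
    rng = np.random.default_rng(seed)
    pop_vals = population["population"].to_numpy(dtype=float)
    per_capita = p.emis_per_capita * pop_vals
    vehicle = p.emis_per_vehicle * p.vehicles_per_capita * pop_vals
    noise = _lognoise(rng, noise_cv, len(pop_vals))
    return pd.DataFrame(
        {
            "year": population["year"],
            "total": (per_capita + vehicle) * noise,
            "per_capita_part": per_capita * noise,
            "vehicle_part": vehicle * noise,
        }
    )


def gen_land_state() -> pd.DataFrame:
    """Land-cover share fixture in the shape of a CORINE class summary
    (shares of the total study area, percent)."""
    return pd.DataFrame(
        [
            ("water_bodies", 85.65),
            ("agricultural", 10.80),
            ("artificialized", 3.05),
            ("urban_fabric", 1.95),
            ("natural_seminatural", 0.41),
            ("urban_green", 0.09),
            ("forests_seminatural_green", 0.50),
        ],
        columns=["land_class", "share_pct"],
    )


def gen_full_fixture(seed: int, outdir: str | Path) -> dict:
    """Write every input file the run/calibrate/assess path consumes, plus a
    ground-truth manifest of the generating parameters (for recovery tests).

    Returns the manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = default_parameters()

    observed, projection = gen_population_series(
        P0=params.initial.population0,
        birth_rate=params.population.birth_rate,
        death_rate=params.population.base_death_rate,
        seed=seed,
    )
    observed.to_csv(outdir / "population_observed.csv", index=False)
    projection.to_csv(outdir / "population_projection.csv", index=False)
    gen_emissions_series(observed, params, seed=seed + 1).to_csv(
        outdir / "emissions.csv", index=False
    )
    gen_land_state().to_csv(outdir / "land_state.csv", index=False)
    default_table().to_csv(outdir / "valuation_table.csv")
    params.to_yaml(outdir / "parameters.yaml")

    manifest = {
        "seed": int(seed),
        "true_parameters": {
            "P0": params.initial.population0,
            "birth_rate": params.population.birth_rate,
            "death_rate": params.population.base_death_rate,
            "noise_cv": 0.01,
        },
        "files": [
            "population_observed.csv",
            "population_projection.csv",
            "emissions.csv",
            "land_state.csv",
            "valuation_table.csv",
            "parameters.yaml",
        ],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
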