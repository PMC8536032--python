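"""Calibration of the demographic core and validation against projections.

``fit`` adjusts the free demographic rates so the simulated population
series matches an observed annual series in least-squares sense on relative
errors (scale-free objective), using bounded local optimisation from five
fixed multi-starts — deterministic by construction. When the observed table
also carries annual ``births``/``deaths`` counts they enter the objective,
which makes the birth and death rates separately identifiable (a population
series alone pins down only their difference).

``validate`` mirrors the study's check: the calibrated run is compared with
an independent projection series and passes if every yearly absolute
percentage error stays below 10%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import ParameterSet, default_parameters
from .synthetic_data import demographic_series

_FITTABLE = ("birth_rate", "base_death_rate")


@dataclass
class FitResult:
    params: ParameterSet
    fitted: dict[str, float]
    objective: float
    converged: bool
    message: str
    residuals: pd.DataFrame = field(repr=False)

    def report(self) -> dict:
        return {
            "fitted": self.fitted,
            "objective": self.objective,
            "converged": self.converged,
            "message": self.message,
            "residuals": self.residuals.to_dict(orient="list"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)


def _objective(theta, names, observed, base):
    rates = {"birth_rate": base.birth_rate, "base_death_rate": base.base_death_rate}
    rates.update(dict(zip(names, theta)))
    sim = demographic_series(
        observed["population"].iloc[0],
        rates["birth_rate"],
        rates["base_death_rate"],
        len(observed),
    )
    total = 0.0
    for obs_col, sim_col in (
        ("population", "population"),
        ("births", "births"),
        ("deaths", "deaths"),
    ):
        if obs_col in observed.columns:
            rel = (sim[sim_col].to_numpy() - observed[obs_col].to_numpy()) / observed[
                obs_col
            ].to_numpy()
            total += float(rel @ rel)
    return total


def fit(
    observed: pd.DataFrame,
    free_params: tuple[str, ...] = ("birth_rate", "base_death_rate"),
    bounds: dict[str, tuple[float, float]] | None = None,
    base_params: ParameterSet | None = None,
) -> FitResult:
    """Fit the free demographic rates to an observed annual series.

    ``observed`` needs (year, population) columns; ``births``/``deaths``
    annual-count columns are used when present. The fitted rates are folded
    into a copy of ``base_params``.
    """
    if len(observed) == 0:
        raise ValueError("observed series is empty")
    if len(free_params) < 2:
        raise ValueError("at least two free parameters are required")
    unknown = set(free_params) - set(_FITTABLE)
    if unknown:
        raise ValueError(
            f"cannot fit {sorted(unknown)}; fittable parameters are {_FITTABLE}"
        )
    if observed["population"].min() <= 0:
        raise ValueError("observed population must be positive")

    base_params = base_params or default_parameters()
    base = base_params.population
    bounds = bounds or {name: (1e-4, 0.05) for name in free_params}
    lo = np.array([bounds[n][0] for n in free_params])
    hi = np.array([bounds[n][1] for n in free_params])

    # five fixed multi-starts: centre plus the four box corners (2 params)
    fracs = [
        np.full(len(free_params), 0.5),
        np.full(len(free_params), 0.15),
        np.full(len(free_params), 0.85),
    ]
    if len(free_params) >= 2:
        f = np.full(len(free_params), 0.15)
        f[0] = 0.85
        fracs.append(f.copy())
        f = np.full(len(free_params), 0.85)
        f[0] = 0.15
        fracs.append(f)

    best = None
    for frac in fracs:
        x0 = lo + frac * (hi - lo)
        res = minimize(
            _objective,
            x0,
            args=(free_params, observed, base),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    fitted = dict(zip(free_params, (float(v) for v in best.x)))
    pop_params = dataclasses.replace(base, **fitted)
    sim = demographic_series(
        observed["population"].iloc[0],
        pop_params.birth_rate,
        pop_params.base_death_rate,
        len(observed),
    )
    residuals = pd.DataFrame(
        {
            "year": observed["year"].to_numpy(),
            "observed": observed["population"].to_numpy(),
            "simulated": sim["population"].to_numpy(),
        }
    )
    residuals["rel_error"] = (
        residuals["simulated"] - residuals["observed"]
    ) / residuals["observed"]
    return FitResult(
        params=base_params.replace(population=pop_params),
        fitted=fitted,
        objective=float(best.fun),
        converged=bool(best.success),
        message=str(best.message),
        residuals=residuals,
    )


@dataclass
class ValidationResult:
    yearly: pd.DataFrame = field(repr=False)
    mape: float = 0.0
    threshold: float = 0.10
    passed: bool = False


def annual_population(trajectory: pd.DataFrame) -> pd.Series:
    """Year-start (January) population from a monthly trajectory."""
    jan = trajectory[trajectory["month_index"] % 12 == 0]
    return pd.Series(
        jan["population"].to_numpy(), index=jan["year"].to_numpy(), name="population"
    )


def validate(
    simulated: pd.Series | pd.DataFrame,
    projection: pd.DataFrame,
    threshold: float = 0.10,
) -> ValidationResult:
    """Compare a simulated population against a projection series.

    ``simulated`` is either a year-indexed population Series or a full
    trajectory DataFrame. Pass requires every yearly absolute percentage
    error below ``threshold``; MAPE is reported alongside.
    """
    if isinstance(simulated, pd.DataFrame):
        simulated = annual_population(simulated)
    years = projection["year"].to_numpy()
    missing = set(years) - set(simulated.index)
    if missing:
        raise ValueError(f"simulation does not cover projection years {sorted(missing)}")
    sim = simulated.loc[years].to_numpy(dtype=float)
    proj = projection["population"].to_numpy(dtype=float)
    ape = np.abs(sim - proj) / proj
    yearly = pd.DataFrame(
        {"year": years, "projection": proj, "simulated": sim, "ape": ape}
    )
    return ValidationResult(
        yearly=yearly,
        mape=float(ape.mean()),
        threshold=threshold,
        passed=bool((ape < threshold).all()),
    )
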