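"""Generic stock-and-flow integrator.

The engine advances an arbitrary set of named stocks by explicit Euler
stepping (default dt = one month). Flows are pure rate functions of the
current state; a flow between two internal stocks conserves their sum by
construction because the same effective rate is subtracted from the source
and added to the sink. Outflows that would drive a stock negative are
scaled down proportionally so the stock lands exactly at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import pandas as pd

EXTERNAL = "external"

#: absolute floor used when clipping post-step floating-point dust
_NEG_EPS = 1e-9


class EngineError(RuntimeError):
    """Raised on non-finite flow rates or invariant violations mid-run."""


@dataclass
class SimClock:
    """Monthly simulation clock over calendar years.

    ``n_steps`` = (end_year - start_year) * 12 / dt with dt in months.
    """

    start_year: int = 2000
    end_year: int = 2050
    dt: float = 1.0  # months

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = (self.end_year - self.start_year) * 12 / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("horizon is not an integer number of steps")

    @property
    def n_steps(self) -> int:
        return round((self.end_year - self.start_year) * 12 / self.dt)

    def month_of_year(self, year: int) -> int:
        """Month index of January of ``year``."""
        return round((year - self.start_year) * 12 / self.dt)


@dataclass
class SimState:
    """Stock vector plus derived auxiliaries at one time step.

    ``stocks`` holds every level variable by name; ``aux`` holds the named
    derived values recomputed each step; ``flows`` records the effective
    (post-clamping) rates applied during the step that produced this state.
    """

    t: int = 0
    stocks: dict[str, float] = field(default_factory=dict)
    aux: dict[str, float] = field(default_factory=dict)
    flows: dict[str, float] = field(default_factory=dict)

    # convenience accessors for the canonical Santander stocks
    @property
    def population(self) -> float:
        return self.stocks["population"]

    @property
    def air_pollution(self) -> float:
        return self.stocks["air_pollution"]

    @property
    def waste_pollution(self) -> float:
        return self.stocks["waste_pollution"]

    @property
    def area_eco(self) -> float:
        return self.stocks["area_eco"]

    @property
    def area_gi(self) -> float:
        return self.stocks["area_gi"]

    @property
    def area_imp(self) -> float:
        return self.stocks["area_imp"]

    @property
    def area_free(self) -> float:
        return self.stocks["area_free"]

    def copy(self) -> "SimState":
        return SimState(self.t, dict(self.stocks), dict(self.aux), dict(self.flows))


@dataclass(frozen=True)
class FlowSpec:
    """A named transfer between two stocks (or to/from ``external``).

    ``rate(state, params, scenario)`` must be pure and return units/month.
    """

    name: str
    source: str
    sink: str
    rate: Callable[[SimState, Any, Any], float]


AuxFn = Callable[[SimState, Any, Any], dict[str, float]]
PostStep = Callable[[SimState, SimState, dict[str, float], float], None]


def _effective_rates(
    state: SimState,
    params: Any,
    scenario: Any,
    flows: Sequence[FlowSpec],
    dt: float,
) -> dict[str, float]:
    """Evaluate raw rates and clamp outflows so no stock goes negative.

    Clamping is proportional per source stock: if the total demanded outflow
    exceeds (stock/dt + inflows), every outflow from that stock is scaled by
    the same factor. Because a clamped outflow reduces a downstream stock's
    inflow, the scaling is iterated to a (monotone, hence convergent) fixed
    point. Clamped flows are reduced, never redirected.
    """
    raw: dict[str, float] = {}
    for f in flows:
        r = f.rate(state, params, scenario)
        if not math.isfinite(r):
            raise EngineError(
                f"flow '{f.name}' produced a non-finite rate at t={state.t}"
            )
        raw[f.name] = max(0.0, r)

    scale = {f.name: 1.0 for f in flows}
    for _ in range(16):
        changed = False
        for s in state.stocks:
            outs = [f for f in flows if f.source == s]
            if not outs:
                continue
            out_tot = sum(raw[f.name] * scale[f.name] for f in outs)
            if out_tot <= 0.0:
                continue
            inflow = sum(
                raw[f.name] * scale[f.name] for f in flows if f.sink == s
            )
            avail = state.stocks[s] / dt + inflow
            if out_tot > avail * (1.0 + 1e-12):
                factor = max(0.0, avail) / out_tot
                for f in outs:
                    scale[f.name] *= factor
                changed = True
        if not changed:
            break
    return {name: raw[name] * scale[name] for name in raw}


def step(
    state: SimState,
    params: Any,
    scenario: Any,
    flows: Sequence[FlowSpec],
    aux_fn: AuxFn | None = None,
    dt: float = 1.0,
    post_step: PostStep | None = None,
) -> SimState:
    """Advance the state by one step of length ``dt`` months.

    Each stock is updated by (inflows - outflows) * dt using the clamped
    effective rates; auxiliaries are recomputed after the stock update.
    """
    eff = _effective_rates(state, params, scenario, flows, dt)

    new = SimState(t=state.t + 1, stocks=dict(state.stocks), flows=eff)
    for f in flows:
        amount = eff[f.name] * dt
        if f.source != EXTERNAL:
            new.stocks[f.source] -= amount
        if f.sink != EXTERNAL:
            new.stocks[f.sink] += amount
    for name, v in new.stocks.items():
        if v < 0.0:
            if v < -_NEG_EPS:
                raise EngineError(
                    f"stock '{name}' went negative ({v:g}) at t={new.t}"
                )
            new.stocks[name] = 0.0

    if post_step is not None:
        post_step(state, new, eff, dt)
    if aux_fn is not None:
        new.aux = aux_fn(new, params, scenario)
    return new


def run(
    initial: SimState,
    params: Any,
    scenario: Any,
    flows: Sequence[FlowSpec],
    clock: SimClock,
    aux_fn: AuxFn | None = None,
    post_step: PostStep | None = None,
    conserved_groups: Iterable[tuple[str, ...]] = (),
    rtol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate from ``initial`` over the whole clock horizon.

    Returns a trajectory with ``n_steps + 1`` rows (one per month, the
    initial state included), containing every stock, auxiliary and effective
    flow rate. Deterministic given (params, scenario, clock). Conservation
    of each stock group in ``conserved_groups`` is checked at every step to
    relative tolerance ``rtol``; a violation aborts with the step index.
    """
    conserved = [tuple(g) for g in conserved_groups]
    totals = [sum(initial.stocks[s] for s in g) for g in conserved]

    state = initial.copy()
    if aux_fn is not None and not state.aux:
        state.aux = aux_fn(state, params, scenario)

    rows = [_row(state, clock)]
    for _ in range(clock.n_steps):
        state = step(state, params, scenario, flows, aux_fn, clock.dt, post_step)
        for g, tot in zip(conserved, totals):
            now = sum(state.stocks[s] for s in g)
            if abs(now - tot) > rtol * max(abs(tot), 1.0):
                raise EngineError(
                    f"conservation of {g} violated at step {state.t}: "
                    f"{now!r} != {tot!r}"
                )
        rows.append(_row(state, clock))
    return pd.DataFrame(rows)


def _row(state: SimState, clock: SimClock) -> dict[str, float]:
    months = state.t * clock.dt
    year = clock.start_year + int(months) // 12
    month = int(months) % 12 + 1
    out: dict[str, Any] = {
        "month_index": state.t,
        "date": f"{year:04d}-{month:02d}",
        "year": year,
    }
    out.update(state.stocks)
    out.update(state.aux)
    out.update({f"flow_{k}": v for k, v in state.flows.items()})
    return out


def write_trajectory(trajectory: pd.DataFrame, path) -> None:
    """Write a trajectory as CSV, one row per month."""
    trajectory.to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path)
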