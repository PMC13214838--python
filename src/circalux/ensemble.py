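"""Parameter grids, ensemble sweeps and the physiological validity filter.

The study sweeps two 5x5x5 grids of phenotype parameters:

* the sleep grid over mu in [17.5, 19.5], delta in [5, 9], chi in [7, 11]
  (circadian parameters at their defaults), and
* the circadian grid over p in [0.5, 0.7], kappa in [0.4, 0.7], tau_c in
  [23.8, 24.4], each point paired with the fixed sleep parameters
  mu=19.0, delta=6.0, chi=11.0.

The validity filter retains a parameter set only if, at steady state on
the regular 16:8 entrainment schedule, every evaluated day shows at
least 6.5 h of sleep and exactly two sleep/wake switches (one onset, one
offset).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .circadian import CircadianParams
from .engine import SimulationResult, equilibrate, simulate
from .protocols import LightSchedule
from .sleep import SleepParams

__all__ = [
    "GridKind",
    "ParameterGrid",
    "EquilibrationSpec",
    "make_sleep_grid",
    "make_circadian_grid",
    "filter_valid",
    "run_sweep",
    "MIN_SLEEP_H",
    "SWITCHES_PER_DAY",
]

MIN_SLEEP_H = 6.5
SWITCHES_PER_DAY = 2

SLEEP_RANGES = {"mu": (17.5, 19.5), "delta": (5.0, 9.0), "chi": (7.0, 11.0)}
CIRCADIAN_RANGES = {"p": (0.5, 0.7), "kappa": (0.4, 0.7), "tau_c": (23.8, 24.4)}
#: sleep parameters attached to every circadian-grid point
CIRCADIAN_GRID_SLEEP = {"mu": 19.0, "delta": 6.0, "chi": 11.0}


class GridKind(str, Enum):
    SLEEP = "sleep"
    CIRCADIAN = "circadian"


@dataclass(frozen=True)
class ParameterGrid:
    """A full-factorial grid of (CircadianParams, SleepParams) pairs."""

    kind: GridKind
    axes: tuple[tuple[str, np.ndarray], ...]
    points: tuple[tuple[CircadianParams, SleepParams], ...]

    def __len__(self) -> int:
        return len(self.points)

    def frame(self) -> pd.DataFrame:
        """One row per point with the swept parameter values."""
        names = [name for name, _ in self.axes]
        rows = []
        for i, (cp, sp) in enumerate(self.points):
            src = {**cp.to_dict(), **sp.to_dict()}
            rows.append({"set_id": i, **{n: src[n] for n in names}})
        return pd.DataFrame(rows)


def _axis(lo: float, hi: float, n: int = 5) -> np.ndarray:
    return np.linspace(lo, hi, n)


def make_sleep_grid(n_per_axis: int = 5) -> ParameterGrid:
    """5x5x5 = 125 evenly spaced points over the sleep-parameter ranges,
    endpoints inclusive; circadian parameters at their defaults."""
    axes = tuple((name, _axis(*SLEEP_RANGES[name], n_per_axis)) for name in ("mu", "delta", "chi"))
    cp = CircadianParams()
    points = tuple(
        (cp, SleepParams(mu=m, delta=d, chi=c))
        for m, d, c in itertools.product(*(vals for _, vals in axes))
    )
    return ParameterGrid(GridKind.SLEEP, axes, points)


def make_circadian_grid(n_per_axis: int = 5) -> ParameterGrid:
    """5x5x5 = 125 points over (p, kappa, tau_c), each paired with the
    fixed sleep parameters mu=19.0, delta=6.0, chi=11.0."""
    axes = tuple(
        (name, _axis(*CIRCADIAN_RANGES[name], n_per_axis)) for name in ("p", "kappa", "tau_c")
    )
    sp = SleepParams(**CIRCADIAN_GRID_SLEEP)
    points = tuple(
        (CircadianParams(p=p, kappa=k, tau_c=tc), sp)
        for p, k, tc in itertools.product(*(vals for _, vals in axes))
    )
    return ParameterGrid(GridKind.CIRCADIAN, axes, points)


# ---------------------------------------------------------------------------
# validity filter
# ---------------------------------------------------------------------------

def _day_metrics(result: SimulationResult, day_start: float, day_end: float) -> tuple[float, int]:
    """(sleep hours, switch count) for one 24 h window; events at the
    window end belong to the ending window, and sleep minutes are the
    overlap of episodes with the window."""
    sleep_h = 0.0
    for ep in result.sleep_episodes:
        off = ep.offset_h if ep.complete else result.t[-1]
        sleep_h += max(0.0, min(off, day_end) - max(ep.onset_h, day_start))
    ev = result.event_times
    switches = int(np.sum((ev > day_start + 1e-9) & (ev <= day_end + 1e-9)))
    return sleep_h, switches


def filter_valid(
    results: list[SimulationResult],
    lights_on: float = 6.0,
    eval_days: int = 10,
    min_sleep_h: float = MIN_SLEEP_H,
) -> tuple[list[int], pd.DataFrame]:
    """Apply the sleep-duration and two-switch filters.

    A result passes if every evaluated protocol day (24 h windows aligned
    to lights-on, the final ``eval_days`` of the run — its steady state)
    has at least ``min_sleep_h`` hours of sleep and exactly two sleep/wake
    switches.  Returns the retained indices and a per-set report.
    The filter is order-independent and idempotent.
    """
    retained: list[int] = []
    rows = []
    for i, res in enumerate(results):
        t_end = float(res.t[-1])
        n_days_avail = int(t_end // 24.0)
        if n_days_avail < 1:
            raise ValueError("each result must span at least one full protocol day")
        n_eval = min(eval_days, n_days_avail)
        # last n_eval complete lights-on-aligned windows
        last_start = 24.0 * ((t_end - lights_on) // 24.0 - 1) + lights_on
        starts = [last_start - 24.0 * k for k in range(n_eval)]
        ok = True
        reason = "pass"
        min_sleep = np.inf
        for s in starts:
            if s < 0:
                continue
            sleep_h, switches = _day_metrics(res, s, s + 24.0)
            min_sleep = min(min_sleep, sleep_h)
            if sleep_h < min_sleep_h:
                ok, reason = False, f"sleep {sleep_h:.2f} h < {min_sleep_h} h"
                break
            if switches != SWITCHES_PER_DAY:
                ok, reason = False, f"{switches} switches/day"
                break
        if ok:
            retained.append(i)
        rows.append({"set_id": i, "retained": ok, "reason": reason, "min_sleep_h": min_sleep})
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibrationSpec:
    """How each grid point is equilibrated before the protocol run."""

    lights_on: float = 6.0
    n_days: int = 30
    lux: float = 1000.0


def run_sweep(
    grid: ParameterGrid,
    schedule: LightSchedule,
    equil: EquilibrationSpec | None = EquilibrationSpec(),
    dt: float = 0.01,
    store_every: int = 5,
) -> tuple[list[SimulationResult | None], list[tuple[int, str]]]:
    """Equilibrate then simulate every grid point on ``schedule``.

    Results keep grid order and are independent of execution order.
    Per-point failures are recorded (index, message) and leave ``None``
    in the results list rather than aborting the sweep.
    """
    results: list[SimulationResult | None] = []
    failures: list[tuple[int, str]] = []
    for i, (cp, sp) in enumerate(grid.points):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                initial = (
                    equilibrate(cp, sp, equil.lights_on, equil.n_days, dt=dt, lux=equil.lux)
                    if equil is not None
                    else None
                )
            results.append(simulate(schedule, cp, sp, initial=initial, dt=dt, store_every=store_every))
        except Exception as exc:  # recorded, not fatal
            failures.append((i, str(exc)))
            results.append(None)
    return results, failures


def sweep_frame(grid: ParameterGrid, metrics: pd.DataFrame) -> pd.DataFrame:
    """Join per-set metrics onto the grid's parameter table by set_id."""
    return grid.frame().merge(metrics, on="set_id", how="left")
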