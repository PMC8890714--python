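"""Multi-dose (redosing) regimens and dose-interval optimization.

A regimen is a sequence of capsule administrations.  Between events the
model is the linear capsule system; at each event the administered capsules
are added to the survivors of earlier doses (N jumps, C1 and C2 are
continuous).  The dosing interval is tuned by minimizing the squared
deviation of the post-transient IP trough from a target concentration,
S = (C_tgt - C1_min)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .model import (
    ModelState,
    TimeCourse,
    _propagate_linear,
    _refine_peak,
    simulate,
    system_matrix,
)
from .params import PKParameters

__all__ = [
    "DoseSchedule",
    "simulate_redosing",
    "minimum_after_transient",
    "TroughResult",
    "optimize_interval",
    "IntervalOptResult",
]


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered capsule-administration events within a simulation horizon.

    ``events`` is a tuple of (time_days, capsules); the first event is at
    t=0 by convention and all events lie in [0, horizon).
    """

    events: tuple[tuple[float, float], ...]
    horizon: float

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(n)) for t, n in self.events)
        object.__setattr__(self, "events", ev)
        if not ev:
            raise ValueError("schedule needs at least one event")
        times = [t for t, _ in ev]
        if times[0] != 0.0:
            raise ValueError("first dose event must be at t=0")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(n < 0 for _, n in ev):
            raise ValueError("capsule counts must be nonnegative")
        if not self.horizon > times[-1]:
            raise ValueError("all events must fall inside [0, horizon)")

    @classmethod
    def uniform(
        cls, n_doses: int, interval: float, capsules: float, horizon: float
    ) -> "DoseSchedule":
        if n_doses < 1 or interval <= 0:
            raise ValueError("need n_doses >= 1 and interval > 0")
        return cls(
            events=tuple((i * interval, capsules) for i in range(n_doses)),
            horizon=horizon,
        )

    @property
    def interval(self) -> float | None:
        """Common spacing between events, or None if non-uniform/single."""
        times = [t for t, _ in self.events]
        if len(times) < 2:
            return None
        gaps = np.diff(times)
        return float(gaps[0]) if np.allclose(gaps, gaps[0]) else None


def simulate_redosing(
    params: PKParameters,
    schedule: DoseSchedule,
    t_grid,
    method: str = "analytic",
) -> TimeCourse:
    """Piecewise (block) integration of a multi-dose regimen on ``t_grid``.

    Each inter-event block is propagated from the final state of the
    preceding block; at an event the full dose is added to the remaining
    capsules.  Grid points at an event time report the post-dose state.

    ``method="analytic"`` uses the exact matrix-exponential propagator;
    ``method="ode"`` integrates each block with the stiff solver.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if t[0] != 0.0 or t[-1] > schedule.horizon:
        raise ValueError("t_grid must start at 0 and end within the horizon")
    A = system_matrix(params)
    bounds = [tv for tv, _ in schedule.events] + [float(t[-1])]
    doses = {tv: n for tv, n in schedule.events}
    x = np.zeros(3)
    out = np.empty((t.size, 3))
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        x = x.copy()
        x[0] += doses.get(t0, 0.0)
        if t1 <= t0:  # event at/after grid end
            continue
        mask = (t >= t0) & (t < t1)
        if t1 == t[-1]:
            mask |= t == t1
        dts = t[mask] - t0
        if method == "analytic":
            if dts.size:
                out[mask] = _propagate_linear(A, x, dts)
            x = _propagate_linear(A, x, np.array([t1 - t0]))[0]
        elif method == "ode":
            grid = np.union1d(dts, [0.0, t1 - t0])
            tc = simulate(
                params,
                N0=x[0],
                t_grid=grid,
                initial=ModelState(0.0, x[0], x[1], x[2]),
            )
            if dts.size:
                idx = np.searchsorted(grid, dts)
                out[mask] = np.column_stack([tc.N, tc.C1, tc.C2])[idx]
            x = np.array([tc.N[-1], tc.C1[-1], tc.C2[-1]])
        else:
            raise ValueError(f"unknown method {method!r}")
    return TimeCourse(times=t, N=out[:, 0], C1=out[:, 1], C2=out[:, 2], params=params)


@dataclass(frozen=True)
class TroughResult:
    c1_min: float
    t_min: float
    #: True when the trajectory had no interior peak and the global
    #: post-dose minimum was used instead
    monotone_fallback: bool


def minimum_after_transient(
    tc: TimeCourse,
    schedule: DoseSchedule | None = None,
    window_end: float | None = None,
) -> TroughResult:
    """Minimum IP concentration after the initial transient.

    The transient ends at the first local maximum of C1 after the first
    dose; the minimum is searched on [t_peak1, window_end], where
    ``window_end`` defaults to (last event + interval) for uniform
    schedules and to the end of the grid otherwise.  Extrema are refined
    by local quadratic interpolation.
    """
    t, y = tc.times, tc.C1
    if window_end is None:
        window_end = t[-1]
        if schedule is not None and schedule.interval is not None:
            window_end = min(t[-1], schedule.events[-1][0] + schedule.interval)
    interior = np.flatnonzero((y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:])) + 1
    if interior.size == 0:
        j = int(np.argmin(y))
        t_min, y_min = _refine_peak(t, y, j)
        return TroughResult(float(y_min), float(t_min), True)
    i_peak = int(interior[0])
    t_peak, _ = _refine_peak(t, y, i_peak)
    mask = (t >= t_peak) & (t <= window_end)
    if not mask.any():
        # the transient outlasts the scheduled window (doses bunched within
        # the rise phase): everything is transient, so report the level
        # reached at the window's end
        j = int(np.searchsorted(t, window_end, side="right")) - 1
        return TroughResult(float(y[j]), float(t[j]), True)
    idx = np.flatnonzero(mask)
    j = int(idx[int(np.argmin(y[idx]))])
    # C1 is continuous but kinked at dose events, so quadratic refinement is
    # only valid at smooth interior troughs; at an event (which the grid
    # contains exactly) the grid value is the exact pre-dose minimum
    event_times = [te for te, _ in schedule.events] if schedule is not None else []
    span = t[min(j + 1, len(t) - 1)] - t[max(j - 1, 0)]
    at_event = any(abs(t[j] - te) <= span for te in event_times)
    if at_event:
        t_min, y_min = float(t[j]), float(y[j])
    else:
        t_min, y_min = _refine_peak(t, y, j)
        if y_min > y[j]:  # refinement only trusted when it deepens the trough
            t_min, y_min = float(t[j]), float(y[j])
    return TroughResult(float(y_min), float(t_min), False)


@dataclass(frozen=True)
class IntervalOptResult:
    interval: float
    c1_min: float
    score: float


def _trough_for_interval(
    params: PKParameters,
    capsules: float,
    n_doses: int,
    horizon: float,
    interval: float,
    pts_per_day: float,
) -> float:
    sched = DoseSchedule.uniform(n_doses, interval, capsules, horizon)
    n_pts = max(int(round(horizon * pts_per_day)), 200)
    grid = np.linspace(0.0, horizon, n_pts + 1)
    grid = np.union1d(grid, [tv for tv, _ in sched.events])
    tc = simulate_redosing(params, sched, grid)
    return minimum_after_transient(tc, sched).c1_min


def optimize_interval(
    params: PKParameters,
    capsules_per_dose: float,
    n_doses: int,
    horizon: float,
    c_target: float,
    i_min: float = 0.25,
    pts_per_day: float = 50.0,
    scan_resolution: float = 0.05,
) -> IntervalOptResult:
    """Dosing interval minimizing S(I) = (C_tgt - C1_min(I))^2.

    S(I) is non-convex — the post-transient trough can hop between dose
    cycles as I varies — so the feasible range (i_min, horizon/n_doses] is
    scanned at ``scan_resolution`` days and the best bracket is polished
    with bounded scalar minimization.
    """
    if c_target <= 0:
        raise ValueError("c_target must be positive")
    i_max = horizon / n_doses
    if not i_max > i_min:
        raise ValueError("infeasible interval range: horizon/n_doses <= i_min")

    def score(i: float) -> float:
        c_min = _trough_for_interval(
            params, capsules_per_dose, n_doses, horizon, i, pts_per_day
        )
        return (c_target - c_min) ** 2

    n_scan = int(np.ceil((i_max - i_min) / scan_resolution)) + 1
    scan = np.linspace(i_min, i_max, n_scan)
    scan_vals = np.array([score(i) for i in scan])
    if not np.any(np.isfinite(scan_vals)):
        raise RuntimeError("no interval achieved a finite score")
    j = int(np.nanargmin(scan_vals))
    best = (float(scan[j]), float(scan_vals[j]))
    lo = scan[max(j - 1, 0)]
    hi = scan[min(j + 1, n_scan - 1)]
    if hi > lo:
        res = minimize_scalar(score, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-5})
        if np.isfinite(res.fun) and res.fun < best[1]:
            best = (float(res.x), float(res.fun))
    i_star, s_star = best
    c_min = _trough_for_interval(
        params, capsules_per_dose, n_doses, horizon, i_star, pts_per_day
    )
    return IntervalOptResult(interval=i_star, c1_min=c_min, score=s_star)
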