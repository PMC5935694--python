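"""Trajectory integration, the conserved quantity of the classical system,
and the random-immigration ensemble protocol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    ImmigrationMode,
    LVParameters,
    ModelSpec,
    State,
    unguarded_field,
)

__all__ = [
    "Trajectory",
    "EnsembleResult",
    "integrate",
    "conserved_quantity",
    "conserved_series",
    "simulate_random_immigration",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
POINTS_PER_UNIT = 10


@dataclass
class Trajectory:
    """A solved trajectory on a uniform output grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    model: ModelSpec
    solver_stats: dict = field(default_factory=dict)
    guard_tripped: bool = False
    guard_time: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnsembleResult:
    """Per-run trajectories on a shared grid, their pointwise mean, and the
    log of every drawn immigration rate."""

    runs: List[Trajectory]
    times: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    draw_log: pd.DataFrame  # columns: run, interval, c_draw, d_draw

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "x": self.mean_x, "y": self.mean_y})

    def runs_frame(self) -> pd.DataFrame:
        frames = []
        for i, tr in enumerate(self.runs):
            f = tr.to_frame()
            f["run"] = i
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _guard_events(model: ModelSpec):
    events = []
    if model.prey_imm.mode is ImmigrationMode.DENSITY_DEPENDENT:
        def prey_floor(t, z, _f=model.x_floor):
            return z[0] - _f
        prey_floor.terminal = True
        prey_floor.direction = -1
        prey_floor.population = "prey"
        events.append(prey_floor)
    if model.pred_imm.mode is ImmigrationMode.DENSITY_DEPENDENT:
        def pred_floor(t, z, _f=model.x_floor):
            return z[1] - _f
        pred_floor.terminal = True
        pred_floor.direction = -1
        pred_floor.population = "predator"
        events.append(pred_floor)
    return events


def integrate(
    model: ModelSpec,
    x0: float,
    y0: float,
    t_end: float,
    n_out: Optional[int] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "DOP853",
) -> Trajectory:
    """Integrate the deterministic system over [0, t_end].

    Output is sampled on a uniform grid of ``n_out`` points (default 10 per
    time unit).  Under density-dependent immigration a positivity guard
    terminates integration when a density reaches the floor; the partial
    trajectory is returned with ``guard_tripped`` set.
    """
    if not model.is_deterministic:
        raise ValueError("integrate() handles deterministic models; use "
                         "simulate_random_immigration() for pulsed models")
    if x0 <= 0 or y0 <= 0:
        raise ValueError(f"initial abundances must be > 0, got ({x0}, {y0})")
    if n_out is None:
        n_out = int(round(POINTS_PER_UNIT * t_end)) + 1
    t_eval = np.linspace(0.0, t_end, n_out)

    # guard-free evaluation: adaptive trial steps and event localization may
    # probe states marginally below the floor; the terminal event enforces it
    field = unguarded_field(model)

    def fun(t, z):
        return field(z)

    events = _guard_events(model)
    sol = solve_ivp(
        fun, (0.0, t_end), [x0, y0], method=method,
        t_eval=t_eval, rtol=rtol, atol=atol, events=events or None,
    )
    stats = {
        "method": method, "rtol": rtol, "atol": atol,
        "nfev": int(sol.nfev), "status": int(sol.status),
        "message": sol.message,
    }
    guard_tripped = False
    guard_time = None
    if sol.status == 1 and events:  # a terminal event fired
        guard_tripped = True
        for ev, times in zip(events, sol.t_events):
            if len(times):
                guard_time = float(times[0])
                stats["guard_population"] = ev.population
                break
    elif sol.status < 0:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0:g}: "
            f"{sol.message}; last state "
            f"{tuple(sol.y[:, -1]) if sol.y.size else (x0, y0)}"
        )
    return Trajectory(
        times=sol.t, x=sol.y[0], y=sol.y[1], model=model,
        solver_stats=stats, guard_tripped=guard_tripped, guard_time=guard_time,
    )


def conserved_quantity(params: LVParameters, state: State) -> float:
    """First integral V = b*x - m*ln(x) + a*y - r*ln(y) of the classical
    (linear response, no immigration) system."""
    if state.x <= 0 or state.y <= 0:
        raise ValueError("V is defined for x > 0, y > 0")
    return (params.b * state.x - params.m * math.log(state.x)
            + params.a * state.y - params.r * math.log(state.y))


def conserved_series(params: LVParameters, traj: Trajectory) -> np.ndarray:
    """V evaluated along a trajectory (vectorized)."""
    return (params.b * traj.x - params.m * np.log(traj.x)
            + params.a * traj.y - params.r * np.log(traj.y))


def simulate_random_immigration(
    model: ModelSpec,
    x0: float,
    y0: float,
    n_steps: int,
    n_runs: int,
    seed: int,
    points_per_unit: int = POINTS_PER_UNIT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "DOP853",
) -> EnsembleResult:
    """Ensemble of trajectories under piecewise-constant random immigration.

    For each run, at the start of each of ``n_steps`` intervals a fresh rate
    is drawn uniformly from [low, high] for every side in random_pulse mode
    (prey draw first, then predator), the ODE is integrated across the
    interval with that constant rate, and the solver restarts at the
    boundary.  One root seed spawns independent per-run substreams, so a
    fixed seed reproduces every draw and the full result.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    prey_rand = model.prey_imm.is_random
    pred_rand = model.pred_imm.is_random
    if not (prey_rand or pred_rand):
        raise ValueError("model has no random_pulse immigration side")
    intervals = {s.interval for s in (model.prey_imm, model.pred_imm) if s.is_random}
    if len(intervals) > 1:
        raise ValueError("prey and predator random_pulse intervals must match")
    interval = intervals.pop()

    n_sub = max(1, int(round(points_per_unit * interval)))
    times = np.linspace(0.0, n_steps * interval, n_steps * n_sub + 1)

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_runs)]
    runs: List[Trajectory] = []
    log_rows = []
    for run_idx, rng in enumerate(streams):
        xs = np.empty_like(times)
        ys = np.empty_like(times)
        xs[0], ys[0] = x0, y0
        state = (float(x0), float(y0))
        nfev = 0
        for k in range(n_steps):
            c_draw = float(rng.uniform(model.prey_imm.low, model.prey_imm.high)) if prey_rand else None
            d_draw = float(rng.uniform(model.pred_imm.low, model.pred_imm.high)) if pred_rand else None
            log_rows.append({"run": run_idx, "interval": k,
                             "c_draw": c_draw if c_draw is not None else np.nan,
                             "d_draw": d_draw if d_draw is not None else np.nan})
            t0, t1 = k * interval, (k + 1) * interval
            t_eval = times[k * n_sub: (k + 1) * n_sub + 1]
            field = unguarded_field(model, c_draw=c_draw, d_draw=d_draw)

            def fun(t, z, _f=field):
                return _f(z)

            sol = solve_ivp(fun, (t0, t1), state, method=method,
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if sol.status < 0:
                raise RuntimeError(
                    f"run {run_idx}, interval {k}: integration failed: {sol.message}")
            nfev += int(sol.nfev)
            xs[k * n_sub: (k + 1) * n_sub + 1] = sol.y[0]
            ys[k * n_sub: (k + 1) * n_sub + 1] = sol.y[1]
            state = (float(sol.y[0, -1]), float(sol.y[1, -1]))
        runs.append(Trajectory(
            times=times, x=xs, y=ys, model=model,
            solver_stats={"method": method, "rtol": rtol, "atol": atol,
                          "nfev": nfev, "run": run_idx},
        ))
    mean_x = np.mean([tr.x for tr in runs], axis=0)
    mean_y = np.mean([tr.y for tr in runs], axis=0)
    draw_log = pd.DataFrame(log_rows, columns=["run", "interval", "c_draw", "d_draw"])
    return EnsembleResult(runs=runs, times=times, mean_x=mean_x,
                          mean_y=mean_y, draw_log=draw_log)
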