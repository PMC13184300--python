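"""Time integration and trajectory-based feature detection.

This module is the numeric counterpart of the symbolic locus analysis: it
integrates a model through a piecewise-constant actuation schedule and
detects ramps on the resulting time series the traditional way (finite
differences and sign-change bracketing), so symbolic conditions can be
cross-validated against an independent route.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ActuationSchedule, GujerModel, ModelError

__all__ = [
    "Trajectory",
    "SBRScenario",
    "IntegrationError",
    "integrate",
    "detect_ramps_numeric",
    "make_fixture",
    "FIXTURES",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to complete an interval."""


@dataclass(frozen=True)
class Trajectory:
    """Integrated time series: ``times`` (d) and ``values`` (time × N, g m-3)."""

    times: np.ndarray
    values: np.ndarray
    state_names: tuple[str, ...]
    schedule: ActuationSchedule | None = None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.state_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.state_names))
        frame.insert(0, "time", self.times)
        return frame

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class SBRScenario:
    """A sequencing-batch-reactor run: initial state + aeration schedule."""

    initial_state: Mapping[str, float]
    schedule: ActuationSchedule
    duration: float
    seed: int | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ModelError("duration must be positive")
        for vals in self.schedule.values.values():
            if any(v < 0 for v in vals):
                raise ModelError("aeration values must be non-negative")


def integrate(
    model: GujerModel,
    initial_state: Mapping[str, float],
    schedule: ActuationSchedule | None,
    time_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``dx/dt = M·r(x) + z(t)`` over a time grid.

    The actuation schedule is piecewise constant; integration restarts at
    each switch so the solver never steps across a discontinuity.  A stiff-
    capable method (LSODA) at tight tolerance makes the result usable as an
    oracle for the symbolic analysis.

    ``schedule`` maps *actuation symbol names* (e.g. ``"z_O2"``) to interval
    values; ``None`` means all actuation is zero.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ModelError("time grid must be strictly increasing, length >= 2")
    x0 = np.array([float(initial_state[n]) for n in model.states.names])
    if np.any(x0[[s.nonnegative for s in model.states]] < -0.0):
        raise ModelError("initial state must be non-negative")

    f = model.derivative_function()
    zsyms = [s.name for s in model.actuation_symbols()]

    if schedule is None:
        edges = [grid[0], grid[-1]]
    else:
        inner = [t for t in schedule.switch_times if grid[0] < t < grid[-1]]
        edges = [grid[0], *inner, grid[-1]]

    times_out = [grid[0]]
    values_out = [x0]
    x = x0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        zvals = (
            [0.0] * len(zsyms)
            if schedule is None
            else [schedule.value_at(0.5 * (t0 + t1)).get(n, 0.0) for n in zsyms]
        )

        def rhs(t, y, _z=zvals):
            return np.asarray(f(*y, *_z), dtype=float)

        t_eval = grid[(grid > t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(
            rhs, (t0, t1), x, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{t0}, {t1}]: {sol.message}"
            )
        times_out.extend(sol.t.tolist())
        values_out.extend(sol.y.T)
        x = sol.y[:, -1]

    times = np.array(times_out)
    values = np.vstack(values_out)
    # integrator-tolerance undershoot below zero flips Monod-term signs and
    # fabricates positive oxygen derivatives; clamp non-negative states
    nonneg = np.array([s.nonnegative for s in model.states])
    values[:, nonneg] = np.maximum(values[:, nonneg], 0.0)
    # drop duplicate interval-edge points not on the requested grid
    keep = np.isin(np.round(times, 12), np.round(grid, 12))
    keep[0] = True
    return Trajectory(
        times=times[keep],
        values=values[keep],
        state_names=model.states.names,
        schedule=schedule,
    )


def _moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(signal, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + signal.size]
    return out


def detect_ramps_numeric(
    trajectory: Trajectory,
    signal: str,
    smoothing_window: int | None = None,
    switch_exclusion: float | None = None,
    slope_floor_rel: float = 1e-6,
) -> np.ndarray:
    """Detect ramp times on a trajectory via finite differences.

    Central-difference second derivative; crossings are isolated sign changes
    refined by linear interpolation, kept only where the interpolated first
    derivative is positive.  Identically-zero second-derivative segments (a
    straight-line signal) report no ramp.  ``switch_exclusion`` drops
    crossings within a half-window (d) of an actuation switch, where the
    actuation derivative is impulsive.

    Positivity of a finite-difference first derivative is only meaningful
    above the differencing noise, so the slope must exceed
    ``slope_floor_rel`` times the trajectory's peak slope (the symbolic
    route keeps strict positivity; this floor applies to the numeric
    detector only).
    """
    t = trajectory.times
    y = trajectory.column(signal)
    if smoothing_window and smoothing_window > 1:
        y = _moving_average(y, int(smoothing_window))
    d1 = np.gradient(y, t)
    d2 = np.gradient(d1, t)

    scale = np.max(np.abs(d2)) if np.any(d2) else 0.0
    tiny = 1e-12 * (1.0 + scale)
    slope_floor = slope_floor_rel * (np.max(np.abs(d1)) if np.any(d1) else 0.0)

    crossings = []
    for k in range(len(t) - 1):
        a, b = d2[k], d2[k + 1]
        if abs(a) <= tiny and abs(b) <= tiny:
            continue  # flat segment, no isolated crossing
        if a == 0.0 and abs(b) > tiny:
            tc, frac = t[k], 0.0
        elif a * b < 0.0:
            frac = a / (a - b)
            tc = t[k] + frac * (t[k + 1] - t[k])
        else:
            continue
        d1c = d1[k] + frac * (d1[k + 1] - d1[k])
        if d1c > slope_floor:
            crossings.append(tc)

    times = np.array(crossings)
    if switch_exclusion and trajectory.schedule is not None:
        for ts in trajectory.schedule.switch_times:
            times = times[np.abs(times - ts) > switch_exclusion]
    return times


def make_fixture(name: str, seed: int = 0):
    """Reproducible (model, scenario) fixtures: analytic toys and an ASM1 SBR.

    ``asm1_sbr`` draws its initial condition uniformly from the default
    screening ranges (biomass strictly positive) and aerates intermittently,
    as typical for a sequencing batch reactor.
    """
    from .asm1 import asm1_model
    from .screening import default_scan_config
    from .toys import logistic_model, monod_batch_model

    if name == "logistic":
        model = logistic_model(r_g=1.0, K=2.0)
        schedule = ActuationSchedule((0.0, 10.0), {})
        scenario = SBRScenario({"x": 0.02}, schedule, duration=10.0, seed=seed)
        return model, scenario
    if name == "monod_batch":
        model = monod_batch_model()
        schedule = ActuationSchedule((0.0, 2.0), {})
        scenario = SBRScenario({"S": 50.0, "X": 5.0}, schedule, duration=2.0, seed=seed)
        return model, scenario
    if name == "asm1_sbr":
        model = asm1_model("mbc14")
        rng = np.random.default_rng(seed)
        ranges = default_scan_config().ranges
        x0 = {n: 0.0 for n in model.states.names}
        for state, (lo, hi) in ranges.items():
            x0[state] = float(rng.uniform(lo, hi))
        # an SBR carries settled biomass between cycles; resample low draws
        for biomass in ("X_h", "X_a"):
            lo, hi = ranges[biomass]
            x0[biomass] = float(rng.uniform(lo + 0.2 * (hi - lo), hi))
        duration = 1.0
        z_hi = float(rng.uniform(800.0, 2000.0))
        schedule = ActuationSchedule(
            (0.0, 0.25, 0.5, 0.75, duration),
            {"z_O2": (z_hi, 0.0, z_hi, 0.0)},
        )
        scenario = SBRScenario(x0, schedule, duration=duration, seed=seed)
        return model, scenario
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")


FIXTURES = ("logistic", "monod_batch", "asm1_sbr")
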