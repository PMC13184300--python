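"""State-space screening of feature loci.

The feature locus (e.g. the ramp condition pair) is measure-zero in state
space, so uniform draws never hit it.  The scan therefore samples all causal
states but one, and solves the second-derivative equality along the remaining
*solve variable* (default: the signal itself) by sign-change bracketing and
bisection.  Each root with a strictly positive first derivative is a ramp
point; points are then classified true/false positive against the
soft-sensor target threshold, and slope-based retention quantifies how a
minimum-slope filter suppresses false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from collections.abc import Mapping, Sequence
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GujerModel, ModelError
from .symbolic import FeatureSpec, lambdified_conditions

__all__ = [
    "ScanConfig",
    "default_scan_config",
    "load_scan_config",
    "sample_states",
    "ramp_points",
    "classify_points",
    "slope_screen",
    "locus_curves_2d",
    "run_scan",
]


@dataclass
class ScanConfig:
    """Configuration of a state-space scan (ranges in g m-3, days for time)."""

    ranges: dict[str, tuple[float, float]]
    n: int = 10000
    seed: int = 0
    model: str = "mbc14"
    signal: str = "S_O2"
    feature: str = "ramp"
    solve_variable: str = "S_O2"
    target_variable: str = "S_NHx"
    threshold: float = 1.0
    plane: tuple[str, str] = ("S_O2", "S_NHx")
    actuation: dict[str, tuple[float, float]] = field(default_factory=dict)
    slope_thresholds: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 800.0)
    min_slope: float | None = None
    grid_nodes: int = 257

    def __post_init__(self):
        if self.n < 1:
            raise ModelError("sample count must be >= 1")
        if self.threshold <= 0:
            raise ModelError("threshold must be positive")
        for name, (lo, hi) in {**self.ranges, **self.actuation}.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi or lo < 0:
                raise ModelError(f"invalid range for {name!r}: [{lo}, {hi}]")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["ranges"] = {k: list(v) for k, v in self.ranges.items()}
        out["actuation"] = {k: list(v) for k, v in self.actuation.items()}
        out["plane"] = list(self.plane)
        out["slope_thresholds"] = list(self.slope_thresholds)
        return out


def _config_from_mapping(data: Mapping) -> ScanConfig:
    data = dict(data)
    ranges = {k: (float(v[0]), float(v[1])) for k, v in data.pop("ranges").items()}
    act = {
        k: (float(v[0]), float(v[1]))
        for k, v in (data.pop("actuation", {}) or {}).items()
    }
    plane = tuple(data.pop("plane", ("S_O2", "S_NHx")))
    slopes = tuple(float(s) for s in data.pop("slope_thresholds", (0.0, 400.0)))
    min_slope = data.pop("min_slope", None)
    return ScanConfig(
        ranges=ranges,
        actuation=act,
        plane=plane,  # type: ignore[arg-type]
        slope_thresholds=slopes,
        min_slope=None if min_slope is None else float(min_slope),
        **{k: v for k, v in data.items() if v is not None},
    )


def load_scan_config(path: str | Path) -> ScanConfig:
    """Load a scan configuration from YAML."""
    with open(path) as fh:
        return _config_from_mapping(yaml.safe_load(fh))


def default_scan_config() -> ScanConfig:
    """Shipped default: dissolved-oxygen ramp scan over literature ranges."""
    text = (
        resources.files("gujerdsa.data")
        .joinpath("asm1_scan_default.yaml")
        .read_text()
    )
    return _config_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------


def sample_states(
    ranges: Mapping[str, tuple[float, float]], n: int, seed: int
) -> pd.DataFrame:
    """Uniform independent draws per named range; reproducible for a seed.

    Variables are sampled in the mapping's iteration order, one full column
    at a time, so a given (ranges, n, seed) always yields the same table.
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {}
    for name, (lo, hi) in ranges.items():
        lo, hi = float(lo), float(hi)
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ModelError(f"empty range for {name!r}: [{lo}, {hi}]")
        data[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    return pd.DataFrame(data)




def _arg_columns(
    model: GujerModel,
    names: Sequence[str],
    table: Mapping[str, np.ndarray],
    solve_variable: str,
    solve_values: np.ndarray,
):
    """Assemble the lambdify argument list; unknown/unused symbols get 0."""
    args = []
    for name in names:
        if name == solve_variable:
            args.append(solve_values)
        elif name in table:
            args.append(np.asarray(table[name], dtype=float))
        else:
            args.append(0.0)
    return args


def ramp_points(
    model: GujerModel,
    feature: FeatureSpec,
    samples: pd.DataFrame,
    solve_variable: str,
    solve_range: tuple[float, float],
    tolerance: float = 1e-10,
    grid_nodes: int = 257,
    residual_rtol: float = 1e-8,
) -> pd.DataFrame:
    """Solve the feature equality along one variable for every sample.

    For each row of ``samples`` (columns: causal states except the solve
    variable, plus actuation symbols such as ``z_O2``) the second derivative
    is evaluated on a monotone grid of ``grid_nodes`` points over
    ``solve_range``; every sign change is refined by bisection to
    ``tolerance`` (absolute, in solve-variable units) and kept if the first
    derivative is strictly positive there.  Multiple roots per sample are
    allowed.

    Returns one row per ramp point: sample index, all sampled states, the
    solve variable, actuation, ``slope`` (ẋ_signal), ``residual`` (|ẍ_signal|).
    """
    if grid_nodes < 2:
        raise ModelError("grid_nodes must be >= 2")
    _, f1, f2, argnames = lambdified_conditions(model, feature.signal)
    lo, hi = float(solve_range[0]), float(solve_range[1])
    if hi <= lo:
        raise ModelError(f"empty solve range [{lo}, {hi}]")
    n = len(samples)
    grid = np.linspace(lo, hi, grid_nodes)
    cols = {c: samples[c].to_numpy(dtype=float)[:, None] for c in samples.columns}
    vals = f2(*_arg_columns(model, argnames, cols, solve_variable, grid[None, :]))
    vals = np.broadcast_to(np.asarray(vals, dtype=float), (n, grid_nodes))
    with np.errstate(invalid="ignore"):
        sign_change = (vals[:, :-1] * vals[:, 1:]) < 0.0
    # a grid node hitting the root exactly is on-locus by convention
    zero_rows, zero_nodes = np.nonzero(vals == 0.0)
    rows_idx, cell_idx = np.nonzero(sign_change)
    if rows_idx.size == 0 and zero_rows.size == 0:
        return _empty_points(model, samples)

    b_lo = grid[cell_idx].copy()
    b_hi = grid[cell_idx + 1].copy()
    flat = {c: samples[c].to_numpy(dtype=float)[rows_idx] for c in samples.columns}
    f_lo = vals[rows_idx, cell_idx]
    n_iter = max(1, int(np.ceil(np.log2((grid[1] - grid[0]) / max(tolerance, 1e-300)))))
    n_iter = min(n_iter, 200)
    for _ in range(n_iter):
        mid = 0.5 * (b_lo + b_hi)
        f_mid = np.asarray(
            f2(*_arg_columns(model, argnames, flat, solve_variable, mid)), dtype=float
        )
        take_left = f_lo * f_mid <= 0.0
        b_hi = np.where(take_left, mid, b_hi)
        b_lo = np.where(take_left, b_lo, mid)
        f_lo = np.where(take_left, f_lo, f_mid)
    root = 0.5 * (b_lo + b_hi)
    if zero_rows.size:
        root = np.concatenate([root, grid[zero_nodes]])
        rows_idx = np.concatenate([rows_idx, zero_rows])
        flat = {
            c: samples[c].to_numpy(dtype=float)[rows_idx] for c in samples.columns
        }
    residual = np.abs(
        np.asarray(
            f2(*_arg_columns(model, argnames, flat, solve_variable, root)), dtype=float
        )
    )
    residual = np.broadcast_to(residual, root.shape)
    slope = np.asarray(
        f1(*_arg_columns(model, argnames, flat, solve_variable, root)), dtype=float
    )
    slope = np.broadcast_to(slope, root.shape)

    # scale-aware residual acceptance: the equality holds relative to the
    # magnitude of its terms along this sample's grid row
    scale = np.nanmax(np.abs(vals), axis=1)[rows_idx]
    ok = (slope > 0.0) & (residual <= residual_rtol * (1.0 + scale))

    out = {"sample": rows_idx[ok]}
    for name in model.states.names:
        if name == solve_variable:
            out[name] = root[ok]
        elif name in flat:
            out[name] = flat[name][ok]
        else:
            out[name] = np.zeros(int(ok.sum()))
    for name in (s.name for s in model.actuation_symbols()):
        out[name] = flat[name][ok] if name in flat else np.zeros(int(ok.sum()))
    out["slope"] = slope[ok]
    out["residual"] = residual[ok]
    return pd.DataFrame(out)


def _empty_points(model: GujerModel, samples: pd.DataFrame) -> pd.DataFrame:
    cols = (
        ["sample"]
        + list(model.states.names)
        + [s.name for s in model.actuation_symbols()]
        + ["slope", "residual"]
    )
    return pd.DataFrame({c: np.array([]) for c in cols})


def classify_points(
    points: pd.DataFrame, target_variable: str, threshold: float
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label points TP/FP: TP iff the target is at or below the threshold."""
    if threshold <= 0:
        raise ModelError("threshold must be positive")
    points = points.copy()
    if len(points):
        tp = points[target_variable].to_numpy(dtype=float) <= threshold
        points["label"] = np.where(tp, "TP", "FP")
    else:
        points["label"] = pd.Series(dtype=str)
    counts = {
        "TP": int((points["label"] == "TP").sum()),
        "FP": int((points["label"] == "FP").sum()),
    }
    return points, counts


def slope_screen(
    points: pd.DataFrame, slope_thresholds: Sequence[float]
) -> pd.DataFrame:
    """Retention table: per minimum slope, TP/FP counts and fractions kept."""
    if "label" not in points.columns:
        raise ModelError("points must be classified first")
    labels = points["label"].to_numpy() if len(points) else np.array([])
    slopes = points["slope"].to_numpy(dtype=float) if len(points) else np.array([])
    n_tp = int((labels == "TP").sum())
    n_fp = int((labels == "FP").sum())
    rows = []
    for s in slope_thresholds:
        keep = slopes >= float(s)
        tp_kept = int(((labels == "TP") & keep).sum())
        fp_kept = int(((labels == "FP") & keep).sum())
        rows.append(
            {
                "min_slope": float(s),
                "tp_retained": tp_kept,
                "fp_retained": fp_kept,
                "tp_fraction": tp_kept / n_tp if n_tp else np.nan,
                "fp_fraction": fp_kept / n_fp if n_fp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def locus_curves_2d(
    model: GujerModel,
    feature: FeatureSpec,
    plane: tuple[str, str],
    fixed_states: Mapping[str, float],
    plane_ranges: Mapping[str, tuple[float, float]],
    grid_resolution: int = 512,
) -> list[np.ndarray]:
    """Zero-level curves of the feature equality in a 2-D state plane.

    The second derivative is evaluated on a ``grid_resolution``² grid over
    the plane ranges; the 0-level set is extracted by marching squares with
    linear interpolation; vertices where the first derivative is not strictly
    positive are masked, splitting curves.  Returns a list of (k, 2) arrays
    of plane coordinates (x = ``plane[0]``, y = ``plane[1]``); the list may
    be empty.

    ``fixed_states`` holds all other causal states and actuation values.
    """
    from skimage import measure

    _, f1, f2, argnames = lambdified_conditions(model, feature.signal)
    xname, yname = plane
    (x_lo, x_hi) = plane_ranges[xname]
    (y_lo, y_hi) = plane_ranges[yname]
    xs = np.linspace(x_lo, x_hi, grid_resolution)
    ys = np.linspace(y_lo, y_hi, grid_resolution)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    table = {xname: X, yname: Y}
    for k, v in fixed_states.items():
        table[k] = np.full_like(X, float(v))
    grid_vals = np.asarray(
        f2(*_arg_columns(model, argnames, table, "", np.array(0.0))), dtype=float
    )
    grid_vals = np.broadcast_to(grid_vals, X.shape)

    def evaluate(fn, xv, yv):
        table = {xname: xv, yname: yv}
        for k, v in fixed_states.items():
            table[k] = np.full_like(np.asarray(xv, dtype=float), float(v))
        out = np.asarray(
            fn(*_arg_columns(model, argnames, table, "", np.array(0.0))),
            dtype=float,
        )
        return np.broadcast_to(out, np.shape(xv))

    def polish(pts, step, axis):
        """Bisection-polish vertices along one plane axis where the equality
        brackets; marching-squares interpolation alone is too coarse for the
        strict first-derivative mask on steep loci."""
        coord = pts[:, axis]
        lo, hi = coord - step, coord + step
        other = pts[:, 1 - axis]

        def f2_at(c):
            xv = c if axis == 0 else other
            yv = other if axis == 0 else c
            return evaluate(f2, xv, yv)

        f_lo, f_hi = f2_at(lo), f2_at(hi)
        bracket = f_lo * f_hi < 0.0
        a, b, fa = lo.copy(), hi.copy(), f_lo.copy()
        for _ in range(45):
            mid = 0.5 * (a + b)
            fm = f2_at(mid)
            left = fa * fm <= 0.0
            b = np.where(bracket & left, mid, b)
            a = np.where(bracket & ~left, mid, a)
            fa = np.where(bracket & ~left, fm, fa)
        pts = pts.copy()
        pts[bracket, axis] = (0.5 * (a + b))[bracket]
        return pts, bracket

    curves = []
    dx = (x_hi - x_lo) / (grid_resolution - 1)
    dy = (y_hi - y_lo) / (grid_resolution - 1)
    for contour in measure.find_contours(grid_vals, 0.0):
        pts = np.column_stack(
            [
                np.clip(x_lo + contour[:, 0] * dx, x_lo, x_hi),
                np.clip(y_lo + contour[:, 1] * dy, y_lo, y_hi),
            ]
        )
        pts, done = polish(pts, dx, axis=0)
        if not done.all():
            pts2, _ = polish(pts[~done], dy, axis=1)
            pts[~done] = pts2
        pts[:, 0] = np.clip(pts[:, 0], x_lo, x_hi)
        pts[:, 1] = np.clip(pts[:, 1], y_lo, y_hi)
        d1 = evaluate(f1, pts[:, 0], pts[:, 1])
        keep = d1 > 0.0
        # split into maximal runs of kept vertices
        if not keep.any():
            continue
        runs = []
        prev = keep[0]
        run_start = 0
        for i in range(1, len(keep)):
            if keep[i] != prev:
                if prev:
                    runs.append((run_start, i))
                run_start = i
                prev = keep[i]
        if prev:
            runs.append((run_start, len(keep)))
        for a, b in runs:
            if b - a >= 2:
                curves.append(pts[a:b])
    return curves


# ---------------------------------------------------------------------------


def run_scan(model: GujerModel, config: ScanConfig) -> dict:
    """Full screening workflow: sample, solve, classify, slope-screen.

    Returns a dict with ``points`` (classified ramp points), ``counts``,
    ``retention`` (slope table) and ``samples`` (the raw draws).
    """
    feature = FeatureSpec(config.signal, config.feature)
    sample_ranges = {
        k: v for k, v in config.ranges.items() if k != config.solve_variable
    }
    sample_ranges.update(config.actuation)
    samples = sample_states(sample_ranges, config.n, config.seed)
    solve_range = config.ranges[config.solve_variable]
    points = ramp_points(
        model,
        feature,
        samples,
        config.solve_variable,
        solve_range,
        grid_nodes=config.grid_nodes,
    )
    points, counts = classify_points(points, config.target_variable, config.threshold)
    if config.min_slope is not None and len(points):
        points = points[points["slope"] >= config.min_slope].reset_index(drop=True)
        _, counts = classify_points(points, config.target_variable, config.threshold)
    retention = slope_screen(points, config.slope_thresholds)
    return {
        "samples": samples,
        "points": points,
        "counts": counts,
        "retention": retention,
    }
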