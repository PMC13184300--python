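"""Gujer/Petersen-matrix model container and evaluation.

Models have the structure ``dx/dt = M·r(x) + z`` where ``M`` is the N×R
stoichiometric (Gujer/Petersen) matrix, ``r(x)`` the vector of R kinetic rate
expressions over the N states, and ``z`` an exogenous actuation term (e.g.
oxygen transfer by aeration).  The matrix and the rates are held symbolically,
so the same object serves numeric evaluation, symbolic differentiation and
structural graph analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp

from ._expr import ExpressionError, parse_expression

__all__ = [
    "StateVar",
    "StateSpec",
    "GujerModel",
    "ActuationSchedule",
    "ModelError",
    "build_model",
    "eval_rates",
    "first_derivative",
    "read_petersen_csv",
    "read_parameters_csv",
    "read_actuation_csv",
]


class ModelError(ValueError):
    """Raised for structurally invalid model definitions."""


@dataclass(frozen=True)
class StateVar:
    """One model state: name, unit and domain/role metadata."""

    name: str
    unit: str = "g m-3"
    nonnegative: bool = True
    #: measurement-only marker (state influenced by the dynamics but not
    #: influencing them); purely informational, the dependency graph decides.
    measurement: bool = False
    #: soft-sensor target marker (e.g. effluent ammonium).
    target: bool = False


class StateSpec:
    """Ordered list of states shared by the matrix, the rates and ``z``.

    The order is fixed at construction and indexes every vector/matrix in the
    model.  Names must be unique.
    """

    def __init__(self, states: Iterable[StateVar | str]):
        items = [s if isinstance(s, StateVar) else StateVar(str(s)) for s in states]
        names = [s.name for s in items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelError(f"duplicate state name(s): {', '.join(dupes)}")
        self._states = tuple(items)
        self._index = {s.name: i for i, s in enumerate(items)}
        self._symbols = tuple(sp.Symbol(s.name) for s in items)

    def __len__(self) -> int:
        return len(self._states)

    def __iter__(self):
        return iter(self._states)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> StateVar:
        return self._states[self._index[name]]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._states)

    @property
    def symbols(self) -> tuple[sp.Symbol, ...]:
        return self._symbols

    def index(self, name: str) -> int:
        if name not in self._index:
            raise ModelError(f"unknown state {name!r}")
        return self._index[name]

    def symbol(self, name: str) -> sp.Symbol:
        return self._symbols[self.index(name)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StateSpec({list(self.names)!r})"


@dataclass(frozen=True)
class ActuationSchedule:
    """Piecewise-constant actuation for simulation.

    ``times`` are the K+1 interval edges (days, increasing); ``values`` maps a
    state name to its K per-interval actuation values.  Within each interval
    the actuation is constant, hence ``ż = 0`` there.
    """

    times: tuple[float, ...]
    values: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ModelError("schedule times must be increasing with >= 2 edges")
        for name, vals in self.values.items():
            if len(vals) != t.size - 1:
                raise ModelError(
                    f"schedule for {name!r} has {len(vals)} values "
                    f"for {t.size - 1} intervals"
                )

    def value_at(self, t: float) -> dict[str, float]:
        edges = np.asarray(self.times)
        k = int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, edges.size - 2))
        return {name: float(vals[k]) for name, vals in self.values.items()}

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(self.times[1:-1])


@dataclass
class GujerModel:
    """A validated model ``dx/dt = M·r(x) + z``.

    Attributes
    ----------
    states
        Ordered :class:`StateSpec`.
    stoichiometry
        SymPy ``N×R`` matrix; entries are numbers or parameter expressions.
    rates
        Tuple of R SymPy expressions over state and parameter symbols.
    process_names
        One name per rate (matrix column).
    parameters
        Name → value mapping for every parameter symbol used.
    actuation
        Mapping state name → ``(z_expr, zdot_expr)``.  Omitted states have
        ``z = 0``.  Entries may be free symbols (e.g. ``z_O2``) which stay
        free in symbolic work and are bound numerically at evaluation time.
    """

    name: str
    states: StateSpec
    stoichiometry: sp.Matrix
    rates: tuple[sp.Expr, ...]
    process_names: tuple[str, ...]
    parameters: dict[str, float]
    actuation: dict[str, tuple[sp.Expr, sp.Expr]] = field(default_factory=dict)

    def __post_init__(self):
        N, R = self.stoichiometry.shape
        if N != len(self.states):
            raise ModelError(
                f"stoichiometric matrix has {N} rows for {len(self.states)} states"
            )
        if R != len(self.rates):
            raise ModelError(
                f"stoichiometric matrix has {R} columns for {len(self.rates)} rates"
            )
        if len(self.process_names) != R:
            raise ModelError("one process name per rate required")
        declared = set(self.states.symbols) | {
            sp.Symbol(p) for p in self.parameters
        }
        for pname, expr in zip(self.process_names, self.rates):
            stray = sp.sympify(expr).free_symbols - declared
            if stray:
                names = ", ".join(sorted(s.name for s in stray))
                raise ModelError(
                    f"rate {pname!r} uses undeclared symbol(s): {names}"
                )
        for entry in self.stoichiometry:
            stray = sp.sympify(entry).free_symbols - {
                sp.Symbol(p) for p in self.parameters
            }
            if stray:
                names = ", ".join(sorted(s.name for s in stray))
                raise ModelError(
                    f"stoichiometric entry {entry} uses undeclared symbol(s): {names}"
                )
        for name in self.actuation:
            self.states.index(name)  # raises for unknown states
        self._rate_fn = None
        self._xdot_fn = None

    # -- symbolic views -----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_rates(self) -> int:
        return len(self.rates)

    def parameter_subs(self) -> dict[sp.Symbol, float]:
        return {sp.Symbol(k): float(v) for k, v in self.parameters.items()}

    def actuation_symbols(self) -> tuple[sp.Symbol, ...]:
        syms: set[sp.Symbol] = set()
        for z, zdot in self.actuation.values():
            syms |= sp.sympify(z).free_symbols | sp.sympify(zdot).free_symbols
        return tuple(sorted(syms, key=lambda s: s.name))

    def z_expr(self, state: str) -> sp.Expr:
        return sp.sympify(self.actuation.get(state, (sp.Integer(0), 0))[0])

    def zdot_expr(self, state: str) -> sp.Expr:
        return sp.sympify(self.actuation.get(state, (0, sp.Integer(0)))[1])

    def xdot_exprs(self, numeric_params: bool = False) -> list[sp.Expr]:
        """Symbolic ``M·r(x) + z`` per state (actuation symbols stay free)."""
        Mr = self.stoichiometry * sp.Matrix(self.rates)
        out = [Mr[i, 0] + self.z_expr(n) for i, n in enumerate(self.states.names)]
        if numeric_params:
            subs = self.parameter_subs()
            out = [e.subs(subs) for e in out]
        return out

    # -- numeric evaluation -------------------------------------------------

    def _state_array(self, state_values: Mapping[str, float]) -> np.ndarray:
        try:
            x = np.array([float(state_values[n]) for n in self.states.names])
        except KeyError as exc:
            raise ModelError(f"missing state value for {exc.args[0]!r}") from exc
        if not np.all(np.isfinite(x)):
            raise ModelError("state values must be finite")
        flagged = [
            s.name
            for s, v in zip(self.states, x)
            if s.nonnegative and v < 0
        ]
        if flagged:
            warnings.warn(
                f"negative value for non-negative state(s): {', '.join(flagged)}",
                RuntimeWarning,
                stacklevel=3,
            )
        return x

    def rate_function(self):
        """Vectorised numeric ``r(x)`` with parameters bound (cached)."""
        if self._rate_fn is None:
            subs = self.parameter_subs()
            exprs = [sp.sympify(r).subs(subs) for r in self.rates]
            self._rate_fn = sp.lambdify(self.states.symbols, exprs, "numpy")
        return self._rate_fn

    def derivative_function(self):
        """Vectorised numeric ``M·r(x) + z`` with parameters bound (cached).

        Returns a callable ``f(x_1..x_N, z_a1..z_ak)`` where the trailing
        arguments are the model's free actuation symbols in name order.
        """
        if self._xdot_fn is None:
            subs = self.parameter_subs()
            exprs = [e.subs(subs) for e in self.xdot_exprs()]
            args = list(self.states.symbols) + list(self.actuation_symbols())
            self._xdot_fn = sp.lambdify(args, exprs, "numpy")
        return self._xdot_fn


# ---------------------------------------------------------------------------
# construction & tabular I/O


def build_model(
    stoichiometry_table: pd.DataFrame,
    parameters: Mapping[str, float],
    actuation: Mapping[str, tuple[object, object]] | None = None,
    *,
    name: str = "model",
    state_meta: Mapping[str, StateVar] | None = None,
) -> GujerModel:
    """Build a :class:`GujerModel` from a tabular Petersen matrix.

    ``stoichiometry_table`` must have a ``process`` column, a ``rate`` column
    holding the kinetic expression strings, and one column per state holding
    stoichiometric entries (numeric literals or parameter expressions; blank
    cells mean zero).  Rows are processes.

    ``actuation`` maps a state name to ``(z, zdot)`` where each element is a
    number or an expression string; free identifiers that are neither states
    nor parameters are admitted there as actuation symbols (e.g. ``z_O2``).
    """
    cols = list(stoichiometry_table.columns)
    for required in ("process", "rate"):
        if required not in cols:
            raise ModelError(f"stoichiometry table lacks a {required!r} column")
    state_names = [c for c in cols if c not in ("process", "rate")]
    if not state_names:
        raise ModelError("stoichiometry table has no state columns")
    meta = state_meta or {}
    spec = StateSpec([meta.get(n, StateVar(n)) for n in state_names])

    param_syms = {p: sp.Symbol(p) for p in parameters}
    state_syms = {n: spec.symbol(n) for n in state_names}
    rate_scope = {**param_syms, **state_syms}

    rates, procs, columns = [], [], []
    for _, row in stoichiometry_table.iterrows():
        procs.append(str(row["process"]))
        rates.append(parse_expression(str(row["rate"]), rate_scope))
        col = []
        for n in state_names:
            cell = row[n]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                col.append(sp.Integer(0))
            elif isinstance(cell, str) and not cell.strip():
                col.append(sp.Integer(0))
            else:
                col.append(parse_expression(str(cell), param_syms))
        columns.append(col)
    M = sp.Matrix(columns).T  # rows were processes; transpose to N×R

    act: dict[str, tuple[sp.Expr, sp.Expr]] = {}
    if actuation:
        for state, (z, zdot) in actuation.items():
            spec.index(state)
            act[state] = (_parse_actuation(z, rate_scope), _parse_actuation(zdot, rate_scope))

    return GujerModel(
        name=name,
        states=spec,
        stoichiometry=M,
        rates=tuple(rates),
        process_names=tuple(procs),
        parameters={k: float(v) for k, v in parameters.items()},
        actuation=act,
    )


def _parse_actuation(value, scope: Mapping[str, sp.Symbol]) -> sp.Expr:
    if isinstance(value, (int, float)):
        return sp.nsimplify(value, rational=False)
    text = str(value).strip()
    # actuation entries may introduce fresh exogenous symbols (z_O2, zdot_O2)
    import ast as _ast

    names = {
        n.id
        for n in _ast.walk(_ast.parse(text, mode="eval"))
        if isinstance(n, _ast.Name)
    }
    extended = dict(scope)
    for n in names - set(scope):
        extended[n] = sp.Symbol(n)
    return parse_expression(text, extended)


def eval_rates(model: GujerModel, state_values: Mapping[str, float]) -> np.ndarray:
    """Evaluate the rate vector ``r(x)`` at a state (length R, deterministic)."""
    x = model._state_array(state_values)
    out = model.rate_function()(*x)
    return np.asarray(out, dtype=float)


def first_derivative(
    model: GujerModel,
    state_values: Mapping[str, float],
    actuation_values: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Evaluate ``dx/dt = M·r(x) + z`` at a state (length N).

    ``actuation_values`` binds the model's free actuation symbols by name
    (e.g. ``{"z_O2": 100.0}``); unbound symbols default to zero.
    """
    x = model._state_array(state_values)
    given = dict(actuation_values or {})
    zargs = [float(given.pop(s.name, 0.0)) for s in model.actuation_symbols()]
    if given:
        raise ModelError(f"unknown actuation symbol(s): {', '.join(sorted(given))}")
    out = model.derivative_function()(*x, *zargs)
    return np.asarray(out, dtype=float)


# -- CSV front ends ---------------------------------------------------------


def read_petersen_csv(path: str | Path) -> pd.DataFrame:
    """Read a Petersen-matrix CSV (``process, rate, <state columns...>``)."""
    table = pd.read_csv(path, dtype=str, skipinitialspace=True)
    table.columns = [c.strip() for c in table.columns]
    for required in ("process", "rate"):
        if required not in table.columns:
            raise ModelError(f"{path}: missing {required!r} column")
    return table


def read_parameters_csv(path: str | Path) -> dict[str, float]:
    """Read a two-column ``name,value`` parameter CSV (extra columns ignored)."""
    table = pd.read_csv(path, skipinitialspace=True, comment="#")
    if not {"name", "value"} <= set(table.columns):
        raise ModelError(f"{path}: expected columns 'name' and 'value'")
    out = {}
    for _, row in table.iterrows():
        try:
            out[str(row["name"]).strip()] = float(row["value"])
        except (TypeError, ValueError) as exc:
            raise ModelError(
                f"{path}: non-numeric value for parameter {row['name']!r}"
            ) from exc
    return out


def read_actuation_csv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read an actuation CSV with columns ``state, value, derivative``."""
    table = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    if not {"state", "value"} <= set(table.columns):
        raise ModelError(f"{path}: expected columns 'state' and 'value'")
    out = {}
    for _, row in table.iterrows():
        deriv = row.get("derivative", "0")
        if deriv is None or (isinstance(deriv, float) and np.isnan(deriv)):
            deriv = "0"
        out[str(row["state"]).strip()] = (str(row["value"]).strip(), str(deriv).strip())
    return out
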