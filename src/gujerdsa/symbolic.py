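"""Symbolic derivation of signal-feature conditions, without time integration.

For a model ``dx/dt = M·r(x) + z`` the second time derivative follows from
the chain rule::

    d²x/dt² = M·J_r·(M·r(x) + z) + ż

with ``J_r`` the R×N Jacobian of the rates with respect to the states.  A
*ramp* of signal ``x_i`` — a non-saddle inflection point — is the locus

    dx_i/dt > 0  and  d²x_i/dt² = 0 ,

both closed-form expressions in states, parameters and actuation, so the
locus can be screened directly in state space instead of detected on
integrated time series.  Valleys/peaks are the analogous extremum loci
(first derivative zero, second derivative sign fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from ._expr import expression_str
from .model import GujerModel

__all__ = [
    "FeatureSpec",
    "SymbolicConditions",
    "rate_jacobian",
    "second_derivative",
    "ramp_conditions",
    "extremum_conditions",
    "condition_states",
    "structurally_infeasible",
    "lambdified_conditions",
]

_FEATURE_KINDS = ("ramp", "valley", "peak")


@dataclass(frozen=True)
class FeatureSpec:
    """A qualitative signal feature: which state, and which derivative pattern.

    ``ramp``: second derivative zero with strictly positive first derivative.
    ``valley``/``peak``: first derivative zero with positive/negative second
    derivative.
    """

    signal: str
    kind: str = "ramp"

    def __post_init__(self):
        if self.kind not in _FEATURE_KINDS:
            raise ValueError(
                f"unknown feature kind {self.kind!r}; choose from {_FEATURE_KINDS}"
            )


@dataclass(frozen=True)
class SymbolicConditions:
    """Closed-form feature-locus conditions for one signal.

    ``inequality`` is the signal's first time derivative (required strictly
    positive for a ramp); ``equality`` its second time derivative (required
    zero).  ``free_states`` / ``free_actuation`` list exactly the state and
    actuation symbols occurring in either expression, in model state order
    resp. name order.
    """

    signal: str
    kind: str
    inequality: sp.Expr
    equality: sp.Expr
    free_states: tuple[str, ...]
    free_actuation: tuple[str, ...]

    def as_strings(self) -> dict[str, str]:
        """Plain-text export in the model expression grammar."""
        rel = {"ramp": ">", "valley": "=", "peak": "="}[self.kind]
        return {
            "signal": self.signal,
            "kind": self.kind,
            "first_derivative": expression_str(self.inequality),
            "first_derivative_relation": f"{rel} 0",
            "second_derivative": expression_str(self.equality),
        }


def rate_jacobian(model: GujerModel) -> sp.Matrix:
    """R×N Jacobian of the rate vector w.r.t. the states, entrywise cancelled."""
    J = sp.Matrix(model.rates).jacobian(sp.Matrix(model.states.symbols))
    return J.applyfunc(sp.cancel)


def second_derivative(model: GujerModel, signal: str) -> sp.Expr:
    """Symbolic ``d²x_i/dt²`` of a signal, in states/parameters/actuation.

    The first-derivative vector inside the chain rule is eliminated using the
    model equation itself, so the result contains no derivative symbols —
    only states, parameters, ``z_i`` and ``ż_i``.
    """
    i = model.states.index(signal)
    J = rate_jacobian(model)
    xdot = sp.Matrix(model.xdot_exprs())
    expr = (model.stoichiometry[i, :] * J * xdot)[0, 0] + model.zdot_expr(signal)
    return expr


def _free_state_names(model: GujerModel, *exprs: sp.Expr) -> tuple[str, ...]:
    free: set[sp.Symbol] = set()
    for e in exprs:
        free |= sp.sympify(e).free_symbols
    return tuple(n for n in model.states.names if sp.Symbol(n) in free)


def _free_actuation_names(model: GujerModel, *exprs: sp.Expr) -> tuple[str, ...]:
    free: set[sp.Symbol] = set()
    for e in exprs:
        free |= sp.sympify(e).free_symbols
    act = set(model.actuation_symbols())
    return tuple(sorted(s.name for s in free & act))


def ramp_conditions(model: GujerModel, signal: str) -> SymbolicConditions:
    """Ramp-locus conditions for a signal: ``ẋ_i > 0 ∧ ẍ_i = 0``."""
    i = model.states.index(signal)
    ineq = model.xdot_exprs()[i]
    eq = second_derivative(model, signal)
    return SymbolicConditions(
        signal=signal,
        kind="ramp",
        inequality=ineq,
        equality=eq,
        free_states=_free_state_names(model, ineq, eq),
        free_actuation=_free_actuation_names(model, ineq, eq),
    )


def extremum_conditions(model: GujerModel, signal: str, kind: str) -> SymbolicConditions:
    """Valley/peak conditions: ``ẋ_i = 0`` with the second-derivative sign."""
    if kind not in ("valley", "peak"):
        raise ValueError("kind must be 'valley' or 'peak'")
    i = model.states.index(signal)
    eq = model.xdot_exprs()[i]
    ineq = second_derivative(model, signal)
    if kind == "peak":
        ineq = -ineq
    return SymbolicConditions(
        signal=signal,
        kind=kind,
        inequality=ineq,
        equality=eq,
        free_states=_free_state_names(model, ineq, eq),
        free_actuation=_free_actuation_names(model, ineq, eq),
    )


def condition_states(conditions: SymbolicConditions) -> tuple[str, ...]:
    """States occurring in either condition expression (model state order)."""
    return conditions.free_states


def lambdified_conditions(model: GujerModel, signal: str):
    """Vectorised numeric ramp conditions, cached per model and signal.

    Returns ``(conditions, f_first, f_second, arg_names)`` where both
    callables take all model states followed by all actuation symbols (name
    order), parameters already bound.
    """
    cache = model.__dict__.setdefault("_condition_fn_cache", {})
    if signal not in cache:
        conds = ramp_conditions(model, signal)
        ps = model.parameter_subs()
        args = list(model.states.symbols) + list(model.actuation_symbols())
        f1 = sp.lambdify(args, conds.inequality.subs(ps), "numpy")
        f2 = sp.lambdify(args, conds.equality.subs(ps), "numpy")
        cache[signal] = (conds, f1, f2, tuple(s.name for s in args))
    return cache[signal]


def structurally_infeasible(
    model: GujerModel,
    signal: str,
    actuation_zero: bool = True,
) -> bool:
    """Best-effort proof that ``ẋ_signal > 0`` cannot hold on the domain.

    Substitutes numeric parameters, sets actuation symbols to zero (if
    ``actuation_zero``), replaces every non-negative-flagged state by a
    non-negative symbol, and inspects the additive terms of the first
    derivative: if every term is provably non-positive, the strict inequality
    is infeasible over the state domain.  Returns ``False`` when the
    inspection is inconclusive (feasibility is then decided by sampling).
    """
    i = model.states.index(signal)
    expr = model.xdot_exprs()[i].subs(model.parameter_subs())
    if actuation_zero:
        expr = expr.subs({s: 0 for s in model.actuation_symbols()})
    subs = {}
    for sv in model.states:
        assumed = sp.Symbol(sv.name, nonnegative=sv.nonnegative or None)
        subs[model.states.symbol(sv.name)] = assumed
    expr = sp.expand(sp.sympify(expr).subs(subs))
    terms = sp.Add.make_args(expr)
    verdicts = [sp.sympify(t).is_nonpositive for t in terms]
    return all(v is True for v in verdicts)
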