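"""Restricted arithmetic expression grammar shared by all tabular model inputs.

The grammar admits identifiers, numeric literals, ``+ - * / **`` and
parentheses — nothing else (no function calls, no attribute access).  Strings
are validated against the Python ``ast`` before being handed to SymPy, so
errors can name the offending token instead of failing deep inside sympify.
"""

from __future__ import annotations

import ast
from collections.abc import Mapping

import sympy as sp

__all__ = ["ExpressionError", "parse_expression", "expression_str"]


class ExpressionError(ValueError):
    """Raised when an expression violates the grammar or names unknown symbols."""


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARYOPS = (ast.UAdd, ast.USub)


def _check_node(node: ast.AST, source: str) -> None:
    if isinstance(node, ast.Expression):
        _check_node(node.body, source)
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(
                f"operator {type(node.op).__name__!r} not allowed in {source!r}"
            )
        _check_node(node.left, source)
        _check_node(node.right, source)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARYOPS):
            raise ExpressionError(
                f"operator {type(node.op).__name__!r} not allowed in {source!r}"
            )
        _check_node(node.operand, source)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"literal {node.value!r} not allowed in {source!r}")
    elif isinstance(node, ast.Name):
        pass
    else:
        raise ExpressionError(
            f"construct {type(node).__name__!r} not allowed in {source!r}"
        )


def parse_expression(source: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    """Parse ``source`` into a SymPy expression over the declared ``symbols``.

    Parameters
    ----------
    source
        Expression string using the restricted grammar.
    symbols
        Declared identifiers (states, parameters, actuation symbols).  Any
        other identifier raises :class:`ExpressionError` naming the symbol.
    """
    text = str(source).strip()
    if not text:
        raise ExpressionError("empty expression")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse {text!r}: {exc.msg}") from exc
    _check_node(tree, text)
    names = {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}
    unknown = sorted(names - set(symbols))
    if unknown:
        raise ExpressionError(
            f"undeclared symbol(s) {', '.join(unknown)} in expression {text!r}"
        )
    expr = sp.sympify(text, locals=dict(symbols), rational=False)
    return sp.sympify(expr)


def expression_str(expr: sp.Expr) -> str:
    """Render an expression back into the restricted grammar (``**`` powers)."""
    return sp.sstr(expr, order="lex")
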