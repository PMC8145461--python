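"""Built-in intensity/probability functions and a safe expression parser.

Switching intensities ``q_i(x)`` and map-choice probabilities ``p_i(x)`` are
scalar functions of the molecule state ``x = (xi1, xi2, xi3)``.  They can be
given as named built-ins (with parameters) or as restricted arithmetic
expressions in the variables ``x1, x2, x3`` and ``r2 = |x|^2``; arbitrary
code is rejected.
"""

from __future__ import annotations

import ast
import math
from typing import Callable

import numpy as np

__all__ = [
    "StateFunction",
    "constant",
    "inverse_quadratic",
    "logistic",
    "compile_expression",
    "resolve_function",
]

StateFunction = Callable[[np.ndarray], float]


def constant(value: float) -> StateFunction:
    """The constant function ``x -> value``."""
    value = float(value)

    def f(_x) -> float:
        return value

    f.spec = {"name": "constant", "value": value}  # type: ignore[attr-defined]
    return f


def inverse_quadratic(scale: float = 0.5) -> StateFunction:
    """``x -> scale / (1 + |x|^2)``.

    With the default ``scale = 1/2`` this is the canonical place-dependent
    gene-off probability ``p0(x) = 1 / (2 (1 + |x|^2))``: switching to (or
    staying in) the inactive state becomes unlikely at high molecule levels,
    a simple self-activating feedback.
    """
    scale = float(scale)

    def f(x) -> float:
        x = np.asarray(x, dtype=float)
        return scale / (1.0 + float(x @ x))

    f.spec = {"name": "inverse_quadratic", "scale": scale}  # type: ignore[attr-defined]
    return f


def logistic(rate: float = 1.0, midpoint: float = 1.0, height: float = 1.0) -> StateFunction:
    """``x -> height / (1 + exp(-rate (|x|^2 - midpoint)))``, a smooth switch in |x|^2."""
    rate, midpoint, height = float(rate), float(midpoint), float(height)

    def f(x) -> float:
        x = np.asarray(x, dtype=float)
        return height / (1.0 + math.exp(-rate * (float(x @ x) - midpoint)))

    f.spec = {  # type: ignore[attr-defined]
        "name": "logistic",
        "rate": rate,
        "midpoint": midpoint,
        "height": height,
    }
    return f


_ALLOWED_CALLS = {
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "tanh": math.tanh,
}
_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Constant,
    ast.Name,
    ast.Call,
    ast.Load,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.Mod,
    ast.USub,
    ast.UAdd,
)


def compile_expression(expr: str) -> StateFunction:
    """Compile a restricted arithmetic expression into a state function.

    Allowed: numbers, the variables ``x1, x2, x3, r2``, the constants
    ``pi, e``, operators ``+ - * / ** %`` and calls to
    ``exp, log, sqrt, abs, min, max, tanh``.  Anything else (attributes,
    subscripts, comprehensions, double-underscore names, ...) raises
    ``ValueError`` at compile time.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"invalid expression {expr!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValueError(
                f"expression {expr!r} uses disallowed construct {type(node).__name__}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_CALLS:
                raise ValueError(f"expression {expr!r} calls a disallowed function")
            if node.keywords:
                raise ValueError("keyword arguments are not allowed in expressions")
        if isinstance(node, ast.Name):
            if node.id not in ("x1", "x2", "x3", "r2", "pi", "e") and node.id not in _ALLOWED_CALLS:
                raise ValueError(f"expression {expr!r} uses unknown name {node.id!r}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ValueError("only numeric constants are allowed in expressions")
    code = compile(tree, "<state-function>", "eval")
    env = dict(_ALLOWED_CALLS, pi=math.pi, e=math.e)

    def f(x) -> float:
        x = np.asarray(x, dtype=float)
        scope = dict(env, x1=float(x[0]), x2=float(x[1]), x3=float(x[2]), r2=float(x @ x))
        return float(eval(code, {"__builtins__": {}}, scope))

    f.spec = {"name": "expr", "expr": expr}  # type: ignore[attr-defined]
    return f


def resolve_function(spec) -> StateFunction:
    """Build a state function from a config spec.

    Accepts a callable (returned unchanged), a number (constant function),
    or a mapping ``{"name": ..., **params}`` naming one of the built-ins
    (``constant``, ``inverse_quadratic``, ``logistic``) or ``expr``.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return constant(spec)
    if isinstance(spec, dict):
        kind = spec.get("name")
        params = {k: v for k, v in spec.items() if k != "name"}
        if kind == "constant":
            return constant(**params)
        if kind == "inverse_quadratic":
            return inverse_quadratic(**params)
        if kind == "logistic":
            return logistic(**params)
        if kind == "expr":
            return compile_expression(params["expr"])
        raise ValueError(f"unknown function name {kind!r}")
    raise TypeError(f"cannot build a state function from {spec!r}")


def function_spec(f: StateFunction) -> dict:
    """Serializable spec of a function built by this module, if available."""
    return getattr(f, "spec", {"name": "opaque", "repr": repr(f)})
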