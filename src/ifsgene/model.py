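"""Deterministic backbone of the three-stage gene expression model.

The model tracks concentrations of pre-mRNA (``xi1``), mRNA (``xi2``) and
protein (``xi3``) in discrete time steps of length ``delta``.  While the gene
state ``i`` (1 = active, 0 = inactive) is held constant, one step of the
dynamics is the linear difference system

.. math::

    \\xi_1(t+\\delta) &= R i + a\\,\\xi_1(t), \\\\
    \\xi_2(t+\\delta) &= C \\xi_1(t) + b\\,\\xi_2(t), \\\\
    \\xi_3(t+\\delta) &= P \\xi_2(t) + c\\,\\xi_3(t),

with per-coordinate retention factors ``a = 1 - C - mu_PR``, ``b = 1 - mu_R``
and ``c = 1 - mu_P``.  ``R`` is the pre-mRNA synthesis rate of the active
gene, ``C`` and ``P`` are the pre-mRNA->mRNA and mRNA->protein conversion
rates, and ``mu_PR``, ``mu_R``, ``mu_P`` are degradation rates.  All rates are
per time step and dimensionless after scaling.

Because the system is linear and the three retention factors are pairwise
distinct, the solution with constant gene state decomposes into three
geometric modes ``a**(t/delta)``, ``b**(t/delta)``, ``c**(t/delta)`` plus a
constant.  :func:`mode_decomposition` returns these coefficients in closed
form; :func:`flow` evaluates the closed-form solution for any real ``t >= 0``.

The active-gene dynamics has the globally attracting fixed point

.. math::

    w = \\left(\\frac{R}{C+\\mu_{PR}},\\;
              \\frac{RC}{(C+\\mu_{PR})\\mu_R},\\;
              \\frac{PCR}{(C+\\mu_{PR})\\mu_R\\mu_P}\\right),

while the inactive-gene dynamics contracts to the origin; the product box
``[0, w1] x [0, w2] x [0, w3]`` is invariant for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterError",
    "DegenerateParameterError",
    "KineticParams",
    "ReducedParams",
    "ModeDecomposition",
    "reduce_params",
    "fixed_point_w",
    "step",
    "flow",
    "mode_decomposition",
    "to_reduced",
    "from_reduced",
    "symmetry_residual",
    "EXAMPLE1",
]

#: tolerance used when checking the pairwise-distinctness of a, b, c
_DEGENERACY_TOL = 1e-12


class ParameterError(ValueError):
    """Raised when kinetic parameters violate the model's admissibility bounds."""


class DegenerateParameterError(ParameterError):
    """Raised when the retention factors a, b, c are not pairwise distinct.

    With repeated factors the geometric-mode decomposition would need
    confluent (polynomial-times-geometric) terms; such parameter sets are
    outside the scope of this package.
    """


@dataclass(frozen=True)
class KineticParams:
    """Kinetic rate constants of the three-stage expression model.

    All six rates must be strictly positive and satisfy the step-consistency
    bounds ``0 < C + mu_PR < 1``, ``0 < mu_R + P < 1`` and ``0 < mu_P < 1``
    (the number of molecules degraded or converted in one step cannot exceed
    the number present).  The induced retention factors must be pairwise
    distinct (non-degeneracy).
    """

    R: float
    C: float
    P: float
    mu_PR: float
    mu_R: float
    mu_P: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R", "C", "P", "mu_PR", "mu_R", "mu_P", "delta"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value!r}")
        if not 0 < self.C + self.mu_PR < 1:
            raise ParameterError(
                f"C + mu_PR must lie in (0, 1), got {self.C + self.mu_PR!r}"
            )
        if not 0 < self.mu_R + self.P < 1:
            raise ParameterError(
                f"mu_R + P must lie in (0, 1), got {self.mu_R + self.P!r}"
            )
        if not 0 < self.mu_P < 1:
            raise ParameterError(f"mu_P must lie in (0, 1), got {self.mu_P!r}")
        a = 1.0 - self.C - self.mu_PR
        b = 1.0 - self.mu_R
        c = 1.0 - self.mu_P
        _check_distinct(a, b, c)

    def as_dict(self) -> dict[str, float]:
        return {
            "R": self.R,
            "C": self.C,
            "P": self.P,
            "mu_PR": self.mu_PR,
            "mu_R": self.mu_R,
            "mu_P": self.mu_P,
            "delta": self.delta,
        }


@dataclass(frozen=True)
class ReducedParams:
    """Per-coordinate retention (contraction) factors of the reduced system.

    ``a = 1 - C - mu_PR``, ``b = 1 - mu_R``, ``c = 1 - mu_P``; each lies in
    the open interval (0, 1) and they are pairwise distinct.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0 < value < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {value!r}")
        _check_distinct(self.a, self.b, self.c)

    @property
    def factors(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def as_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c}


def _check_distinct(a: float, b: float, c: float) -> None:
    if (
        abs(a - b) <= _DEGENERACY_TOL
        or abs(b - c) <= _DEGENERACY_TOL
        or abs(c - a) <= _DEGENERACY_TOL
    ):
        raise DegenerateParameterError(
            f"retention factors must be pairwise distinct, got a={a!r}, b={b!r}, c={c!r}"
        )


#: canonical worked example: delta=1, R=1, mu_PR=1/4, C=mu_R=1/4, P=mu_P=1/3,
#: giving retention factors (a, b, c) = (1/2, 3/4, 2/3) and fixed point w=(2,2,2)
EXAMPLE1 = KineticParams(
    R=1.0, C=0.25, P=1.0 / 3.0, mu_PR=0.25, mu_R=0.25, mu_P=1.0 / 3.0, delta=1.0
)


def reduce_params(params: KineticParams) -> ReducedParams:
    """Retention factors ``(a, b, c)`` of the reduced diagonal system."""
    return ReducedParams(
        a=1.0 - params.C - params.mu_PR,
        b=1.0 - params.mu_R,
        c=1.0 - params.mu_P,
    )


def fixed_point_w(params: KineticParams) -> np.ndarray:
    """Steady state ``w`` of the active-gene (i=1) dynamics.

    ``w`` is the unique fixed point of :func:`step` with ``i=1`` and the
    ``t -> inf`` limit of :func:`flow` with ``i=1`` from any initial state.
    The inactive-gene fixed point is the origin, and
    ``[0, w1] x [0, w2] x [0, w3]`` is invariant under both maps.
    """
    A = params.C + params.mu_PR
    w1 = params.R / A
    w2 = params.R * params.C / (A * params.mu_R)
    w3 = params.P * params.C * params.R / (A * params.mu_R * params.mu_P)
    return np.array([w1, w2, w3])


def step(params: KineticParams, state, i: int) -> np.ndarray:
    """Advance the molecule state by one time step with gene state ``i``.

    The update uses the *current* gene state: the state at ``t + delta`` is
    computed from ``i(t)``, so a switch taking effect at time ``t`` first
    influences the molecule levels at ``t + delta``.
    """
    _check_gene(i)
    xi = np.asarray(state, dtype=float)
    if xi.shape != (3,):
        raise ValueError(f"state must be a 3-vector, got shape {xi.shape}")
    a = 1.0 - params.C - params.mu_PR
    b = 1.0 - params.mu_R
    c = 1.0 - params.mu_P
    return np.array(
        [
            params.R * i + a * xi[0],
            params.C * xi[0] + b * xi[1],
            params.P * xi[1] + c * xi[2],
        ]
    )


@dataclass(frozen=True)
class ModeDecomposition:
    """Geometric-mode representation of the constant-gene-state solution.

    Each coordinate k of the solution is
    ``xi_k(t) = sum_m coeffs[k, m] * ratios[m]**(t/delta) + const[k]``
    where ``ratios = (a, b, c)``.  The coefficient matrix is lower
    triangular: coordinate 1 involves only the ``a`` mode, coordinate 2 the
    ``a`` and ``b`` modes, coordinate 3 all three.
    """

    ratios: np.ndarray  # (a, b, c)
    coeffs: np.ndarray  # shape (3, 3); coeffs[k, m] multiplies ratios[m]**(t/delta)
    const: np.ndarray  # shape (3,); the t -> inf limit, equal to w * i
    delta: float

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the closed-form solution at (real, nonnegative) time t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        modes = self.ratios ** (t[..., None] / self.delta)
        return modes @ self.coeffs.T + self.const


def mode_decomposition(params: KineticParams, i: int, state) -> ModeDecomposition:
    """Closed-form geometric-mode coefficients for a given start and gene state.

    Solves the constant-``i`` linear system exactly: the returned object
    reproduces the iterated one-step map at every integer multiple of
    ``delta`` and interpolates it for real ``t``.
    """
    _check_gene(i)
    xi = np.asarray(state, dtype=float)
    if xi.shape != (3,):
        raise ValueError(f"state must be a 3-vector, got shape {xi.shape}")
    R, C, P = params.R, params.C, params.P
    A = params.C + params.mu_PR
    muR, muP = params.mu_R, params.mu_P
    red = reduce_params(params)  # raises on degeneracy
    w = fixed_point_w(params)

    coeffs = np.zeros((3, 3))
    # coordinate 1: single mode a
    coeffs[0, 0] = xi[0] - w[0] * i
    # coordinate 2: modes b and a
    coeffs[1, 1] = xi[1] + C / (A - muR) * (xi[0] - R / muR * i)
    coeffs[1, 0] = -C / (A - muR) * (xi[0] - R / A * i)
    # coordinate 3: modes c, b and a
    coeffs[2, 2] = (
        xi[2]
        + P / (muR - muP) * xi[1]
        + P * C / ((muR - muP) * (A - muP)) * xi[0]
        - P * C * R / ((muR - muP) * (A - muP) * muP) * i
    )
    coeffs[2, 1] = (
        -P / (muR - muP) * xi[1]
        - P * C / ((muR - muP) * (A - muR)) * xi[0]
        + P * C * R / ((A - muR) * (muR - muP) * muR) * i
    )
    coeffs[2, 0] = P * C / ((A - muR) * (A - muP)) * (xi[0] - R / A * i)

    return ModeDecomposition(
        ratios=red.factors, coeffs=coeffs, const=w * i, delta=params.delta
    )


def flow(params: KineticParams, t, state, i: int) -> np.ndarray:
    """Closed-form solution ``pi_i(t, state)`` of the constant-``i`` system.

    Defined for all real ``t >= 0``; at ``t = n * delta`` it coincides with
    ``n`` applications of :func:`step`.
    """
    return mode_decomposition(params, i, state).evaluate(t)


def to_reduced(state, params: KineticParams) -> np.ndarray:
    """Map molecule concentrations to the starred (reduced) coordinates.

    The reduced system advances by the diagonal affine maps
    ``xi_k* -> r_k xi_k* + u_k i`` with ``r = (a, b, c)``; the change of
    variables is the invertible lower-triangular linear map

    ``xi1 = R(a-c)(a-b) xi1*``,
    ``xi2 = CR(a-c) xi1* + CR(b-c) xi2*``,
    ``xi3 = PCR (xi1* + xi2* + xi3*)``.
    """
    xi = np.asarray(state, dtype=float)
    return np.linalg.solve(_reduction_matrix(params), xi)


def from_reduced(reduced_state, params: KineticParams) -> np.ndarray:
    """Inverse of :func:`to_reduced`."""
    xs = np.asarray(reduced_state, dtype=float)
    return _reduction_matrix(params) @ xs


def _reduction_matrix(params: KineticParams) -> np.ndarray:
    red = reduce_params(params)
    a, b, c = red.a, red.b, red.c
    R, C, P = params.R, params.C, params.P
    return np.array(
        [
            [R * (a - c) * (a - b), 0.0, 0.0],
            [C * R * (a - c), C * R * (b - c), 0.0],
            [P * C * R, P * C * R, P * C * R],
        ]
    )


def symmetry_residual(params: KineticParams, t, state) -> float:
    """Residual of the on/off flow symmetry ``pi_0(t, w - xi) = w - pi_1(t, xi)``.

    Both gene states share the same linear part, so the inactive-gene flow
    started from the reflected state ``w - xi`` mirrors the active-gene flow
    from ``xi`` through ``w/2``.  Returns the Euclidean norm of the
    difference of the two sides; it is zero up to rounding for all valid
    parameters.
    """
    xi = np.asarray(state, dtype=float)
    w = fixed_point_w(params)
    lhs = flow(params, t, w - xi, 0)
    rhs = w - flow(params, t, xi, 1)
    return float(np.linalg.norm(lhs - rhs))


def _check_gene(i: int) -> None:
    if i not in (0, 1):
        raise ValueError(f"gene state must be 0 or 1, got {i!r}")
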