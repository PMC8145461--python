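"""Closed-form geometry of the invariant set of the reduced system.

With retention factors ``a, b, c`` the gene-on map ``S1`` has the fixed
point

``v = (1/((a-c)(a-b)(1-a)), 1/((b-a)(b-c)(1-b)), 1/((c-a)(c-b)(1-c)))``

and the real-time flows compose so neatly that every state reachable after
two gene switches — and hence the whole invariant solid ``A`` — admits the
explicit parametrization

``A = { (v1 (x - y + z),
         v2 (x^eb - y^eb + z^eb),
         v3 (x^ec - y^ec + z^ec)) : 1 >= x >= y >= z >= 0 }``

with exponents ``eb = log_a b`` and ``ec = log_a c``.  The equivalent
complementary form replaces ``x - y + z`` by ``1 - x + y - z`` (and likewise
with exponents), which is the exact statement of the symmetry ``v - A = A``
through the center ``v/2``.  The boundary consists of the two one-switch
surfaces ``A0`` (``z = 0``) and ``A1`` (``x = 1``), images of each other
under the same point reflection.

Everything here lives in reduced coordinates; use the model module's linear
change of variables to overlay with molecule-level trajectories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .maps import PointCloud
from .model import ReducedParams

__all__ = [
    "AttractorSpec",
    "AttractorCloud",
    "v_vector",
    "attractor_point",
    "attractor_point_alt",
    "boundary_surface",
    "two_switch_state",
    "attractor_cloud",
    "membership",
]


def v_vector(reduced: ReducedParams) -> np.ndarray:
    """Fixed point ``v`` of the gene-on map ``S1`` in reduced coordinates."""
    a, b, c = reduced.a, reduced.b, reduced.c
    return np.array(
        [
            1.0 / ((a - c) * (a - b) * (1.0 - a)),
            1.0 / ((b - a) * (b - c) * (1.0 - b)),
            1.0 / ((c - a) * (c - b) * (1.0 - c)),
        ]
    )


@dataclass(frozen=True)
class AttractorSpec:
    """Derived geometric data of the invariant solid ``A``."""

    reduced: ReducedParams

    @property
    def v(self) -> np.ndarray:
        return v_vector(self.reduced)

    @property
    def exponents(self) -> np.ndarray:
        """Per-coordinate exponents ``(1, log_a b, log_a c)``; all positive."""
        a, b, c = self.reduced.a, self.reduced.b, self.reduced.c
        return np.array([1.0, math.log(b) / math.log(a), math.log(c) / math.log(a)])

    @property
    def center(self) -> np.ndarray:
        """Symmetry center ``v / 2`` of ``A``."""
        return self.v / 2.0


def _check_ordered(s: np.ndarray, tol: float = 1e-12) -> None:
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    ok = (x <= 1 + tol) & (y <= x + tol) & (z <= y + tol) & (z >= -tol)
    if not np.all(ok):
        raise ValueError("simplex coordinates must satisfy 1 >= x >= y >= z >= 0")


def _powers(s: np.ndarray, exponents: np.ndarray) -> np.ndarray:
    """``s[..., k] ** exponents[k]`` with the convention 0**e = 0 (e > 0)."""
    base = np.clip(np.asarray(s, dtype=float), 0.0, None)
    return base ** exponents


def attractor_point(spec: AttractorSpec, s) -> np.ndarray:
    """Point of ``A`` at ordered simplex coordinates ``s = (x, y, z)``.

    ``(0,0,0)`` maps to the origin and ``(1,1,1)`` to ``v``.  Accepts an
    (n, 3) array of coordinate triples.
    """
    s = np.asarray(s, dtype=float)
    _check_ordered(s)
    return spec.v * (
        _powers(s[..., 0, None], spec.exponents)
        - _powers(s[..., 1, None], spec.exponents)
        + _powers(s[..., 2, None], spec.exponents)
    )


def attractor_point_alt(spec: AttractorSpec, s) -> np.ndarray:
    """Complementary parametrization; identically ``v - attractor_point(s)``."""
    s = np.asarray(s, dtype=float)
    _check_ordered(s)
    return spec.v * (
        1.0
        - _powers(s[..., 0, None], spec.exponents)
        + _powers(s[..., 1, None], spec.exponents)
        - _powers(s[..., 2, None], spec.exponents)
    )


def boundary_surface(spec: AttractorSpec, which: str, alpha, beta) -> np.ndarray:
    """Point(s) on the one-switch boundary surface ``A0`` or ``A1``.

    ``A0`` collects the states reachable from the origin with a single
    on-then-off switch, ``A1`` those from ``v`` with off-then-on; they are
    swapped by the reflection through ``v/2``:
    ``A0(alpha, beta) + A1(alpha, beta) = v``.  Requires
    ``1 >= alpha >= beta >= 0``.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha > 1) or np.any(beta > alpha) or np.any(beta < 0):
        raise ValueError("surface parameters must satisfy 1 >= alpha >= beta >= 0")
    pa = _powers(alpha[..., None], spec.exponents)
    pb = _powers(beta[..., None], spec.exponents)
    if which == "A0":
        return spec.v * (pa - pb)
    if which == "A1":
        return spec.v * (1.0 - pa + pb)
    raise ValueError(f"surface must be 'A0' or 'A1', got {which!r}")


def two_switch_state(
    reduced: ReducedParams, start_i: int, t1: float, t2: float, t3: float, x
) -> np.ndarray:
    """Closed-form endpoint of three constant-gene flow segments.

    Runs the reduced flow for real durations ``t1, t2, t3`` with gene states
    ``start_i, 1 - start_i, start_i``.  Coordinate-wise, with ratio
    ``r in {a, b, c}`` and fixed-point component ``v_k``:

    * start gene on (``i=1``):  ``v_k (1 - r^t3 + r^(t2+t3) - r^(t1+t2+t3)) + r^(t1+t2+t3) x_k``
    * start gene off (``i=0``): ``v_k (r^t3 - r^(t2+t3)) + r^(t1+t2+t3) x_k``
    """
    if start_i not in (0, 1):
        raise ValueError("start_i must be 0 or 1")
    if min(t1, t2, t3) < 0:
        raise ValueError("durations must be nonnegative")
    r = reduced.factors
    v = v_vector(reduced)
    x = np.asarray(x, dtype=float)
    r3 = r ** t3
    r23 = r ** (t2 + t3)
    r123 = r ** (t1 + t2 + t3)
    if start_i == 1:
        return v * (1.0 - r3 + r23 - r123) + r123 * x
    return v * (r3 - r23) + r123 * x


@dataclass
class AttractorCloud:
    """A deterministic sample of ``A`` with its per-axis image-space spacing."""

    cloud: PointCloud
    axis_spacing: np.ndarray  # max adjacent image increment along each axis
    n_per_axis: int
    spec: AttractorSpec


def _grid_levels(spec: AttractorSpec, n_per_axis: int) -> np.ndarray:
    """Grid levels on [0, 1], warped so image increments stay bounded.

    The power maps ``t -> t^e`` with ``e < 1`` have unbounded slope at 0, so
    a uniform grid would leave large image gaps near the origin.  Using
    ``t_k = (k/n)^(1/e_min)`` with ``e_min = min(1, eb, ec)`` makes the
    steepest coordinate uniform and every other coordinate smoother.
    """
    e_min = float(min(1.0, spec.exponents.min()))
    u = np.linspace(0.0, 1.0, n_per_axis)
    return u ** (1.0 / e_min)


def attractor_cloud(spec: AttractorSpec, n_per_axis: int = 101) -> AttractorCloud:
    """Evaluate the solid-``A`` parametrization on the ordered simplex grid.

    Enumerates all level triples with ``x >= y >= z`` from a warped
    ``n_per_axis``-level grid and maps them through the parametrization.
    The returned object carries the per-axis spacing (largest image-space
    increment between adjacent levels), the natural length unit for
    nearest-neighbor membership tests.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be at least 2")
    levels = _grid_levels(spec, n_per_axis)
    ix, iy, iz = np.meshgrid(
        np.arange(n_per_axis), np.arange(n_per_axis), np.arange(n_per_axis), indexing="ij"
    )
    keep = (ix >= iy) & (iy >= iz)
    s = np.column_stack([levels[ix[keep]], levels[iy[keep]], levels[iz[keep]]])
    pts = attractor_point(spec, s)
    spacing = np.array(
        [
            abs(spec.v[k]) * np.max(np.diff(levels ** spec.exponents[k]))
            for k in range(3)
        ]
    )
    return AttractorCloud(
        cloud=PointCloud(points=pts), axis_spacing=spacing, n_per_axis=n_per_axis, spec=spec
    )


def membership(
    spec: AttractorSpec,
    points,
    tol: float = 3.0,
    reference: AttractorCloud | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-based membership test against a reference grid cloud of ``A``.

    Coordinates are rescaled by the reference cloud's per-axis spacing, so
    distances are in grid-spacing units and ``tol`` is a multiple of the
    grid resolution (default 3).  Returns ``(inside, distance)`` arrays
    (scalars for a single point): ``inside`` is true where the scaled
    nearest-neighbor distance is at most ``tol``.
    """
    if reference is None:
        reference = attractor_cloud(spec)
    if tol <= 1.0:
        warnings.warn(
            f"membership tolerance {tol} is at or below the grid resolution; "
            "expect false negatives",
            stacklevel=2,
        )
    scale = reference.axis_spacing
    tree = cKDTree(reference.cloud.points / scale)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, _ = tree.query(pts / scale, workers=-1)
    inside = dist <= tol
    if np.asarray(points).ndim == 1:
        return bool(inside[0]), float(dist[0])
    return inside, dist
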