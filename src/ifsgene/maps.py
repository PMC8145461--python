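"""The two-map iterated function system in reduced coordinates.

In the starred coordinates the gene-off and gene-on one-step maps become the
diagonal affine contractions

``S_i(x) = (a x1 + u1 i,  b x2 + u2 i,  c x3 + u3 i)``,   i in {0, 1},

with translation ``u = (1/((a-c)(a-b)), 1/((b-a)(b-c)), 1/((c-a)(c-b)))``.
Both maps contract Euclidean distance by ``max{a, b, c} < 1``; ``S0`` fixes
the origin and ``S1`` fixes ``v = u / (1-a, 1-b, 1-c)``.  The pair therefore
has a unique nonempty compact attractor ``K`` with ``K = S0(K) ∪ S1(K)``,
approachable either by iterating the Hutchinson set operator
(:func:`hutchinson_iterate`) or by the chaos game (:func:`chaos_game`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .model import KineticParams, ReducedParams, reduce_params

__all__ = [
    "AffineMapPair",
    "PointCloud",
    "apply_map",
    "contraction_constant",
    "hutchinson_iterate",
    "chaos_game",
    "hausdorff_distance",
]


@dataclass(frozen=True)
class AffineMapPair:
    """The gene-off/gene-on contraction pair ``S0``, ``S1``."""

    reduced: ReducedParams

    @classmethod
    def from_kinetic(cls, params: KineticParams) -> "AffineMapPair":
        return cls(reduced=reduce_params(params))

    @property
    def linear(self) -> np.ndarray:
        """Diagonal of the shared linear part, ``(a, b, c)``."""
        return self.reduced.factors

    @property
    def translation(self) -> np.ndarray:
        """The ``S1`` translation vector ``u``; ``S0`` has zero translation."""
        a, b, c = self.reduced.a, self.reduced.b, self.reduced.c
        return np.array(
            [
                1.0 / ((a - c) * (a - b)),
                1.0 / ((b - a) * (b - c)),
                1.0 / ((c - a) * (c - b)),
            ]
        )

    def apply(self, i: int, x) -> np.ndarray:
        """Evaluate ``S_i`` at a point or an (n, 3) array of points."""
        if i not in (0, 1):
            raise ValueError(f"map index must be 0 or 1, got {i!r}")
        pts = np.asarray(x, dtype=float)
        return pts * self.linear + self.translation * i

    def fixed_point(self, i: int) -> np.ndarray:
        """Fixed point of ``S_i``: origin for i=0, ``v`` for i=1."""
        if i == 0:
            return np.zeros(3)
        return self.translation / (1.0 - self.linear)


@dataclass
class PointCloud:
    """A finite set of 3-D points with optional normalized weights."""

    points: np.ndarray
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.points),):
                raise ValueError("weights must have one entry per point")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must have positive total mass")
            self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.points)


def apply_map(pair: AffineMapPair, i: int, x) -> np.ndarray:
    """Functional alias for :meth:`AffineMapPair.apply`."""
    return pair.apply(i, x)


def contraction_constant(reduced: ReducedParams) -> float:
    """Common Lipschitz constant of ``S0`` and ``S1``: ``max{a, b, c}``."""
    return float(max(reduced.a, reduced.b, reduced.c))


def _dedup(points: np.ndarray, resolution: float) -> np.ndarray:
    """Merge points that fall in the same cell of a uniform grid."""
    if resolution <= 0:
        return points
    keys = np.round(points / resolution).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(idx)]


def hutchinson_iterate(
    pair: AffineMapPair,
    seed_cloud: PointCloud,
    n_iter: int,
    dedup_resolution: float = 1e-4,
    max_points: int = 2_000_000,
) -> PointCloud:
    """Iterate the set operator ``A -> S0(A) ∪ S1(A)`` from a seed cloud.

    Starting from any nonempty compact seed the iterates converge to the
    attractor ``K`` in the Hausdorff metric, the distance shrinking by at
    least ``max{a, b, c}`` per iteration.  Points closer than
    ``dedup_resolution`` (on a uniform grid) are merged after every
    iteration to keep the cloud size bounded.

    Raises ``RuntimeError`` if the deduplicated cloud would exceed
    ``max_points``.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be nonnegative")
    if len(seed_cloud) == 0:
        raise ValueError("seed cloud must be nonempty")
    pts = seed_cloud.points
    for _ in range(n_iter):
        pts = np.vstack([pair.apply(0, pts), pair.apply(1, pts)])
        pts = _dedup(pts, dedup_resolution)
        if len(pts) > max_points:
            raise RuntimeError(
                f"Hutchinson cloud exceeded the budget of {max_points} points; "
                "coarsen dedup_resolution or reduce n_iter"
            )
    return PointCloud(points=pts)


def chaos_game(
    pair: AffineMapPair,
    choice_policy: Callable[[np.ndarray], float] | float,
    n_points: int,
    burn_in: int = 1000,
    seed: int | np.random.Generator = 0,
    start=(0.0, 0.0, 0.0),
) -> PointCloud:
    """Sample the attractor by randomly iterating ``S0``/``S1`` from one seed.

    At each step the gene-off map ``S0`` is chosen with probability
    ``p0(x)`` evaluated at the *current* point ``x`` (``choice_policy`` may
    be a constant for the classical place-independent game), and the chosen
    map is applied.  The first ``burn_in`` post-start points are discarded;
    the remaining ``n_points`` orbit points are returned.  Reproducible for
    a fixed integer ``seed``.
    """
    if n_points < 0 or burn_in < 0:
        raise ValueError("n_points and burn_in must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p0 = (lambda _x, _p=float(choice_policy): _p) if np.isscalar(choice_policy) else choice_policy

    x = np.asarray(start, dtype=float)
    lin = pair.linear
    u = pair.translation
    total = burn_in + n_points
    out = np.empty((n_points, 3))
    uniforms = rng.random(total)
    for k in range(total):
        p = p0(x)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"choice probability {p!r} outside [0, 1] at {x!r}")
        i = 0 if uniforms[k] < p else 1
        x = x * lin + u * i
        if k >= burn_in:
            out[k - burn_in] = x
    return PointCloud(points=out)


def hausdorff_distance(cloud_a: PointCloud, cloud_b: PointCloud) -> float:
    """Symmetric Hausdorff distance between two point clouds."""
    if len(cloud_a) == 0 or len(cloud_b) == 0:
        raise ValueError("Hausdorff distance requires nonempty clouds")
    d_ab = directed_hausdorff(cloud_a.points, cloud_b.points)[0]
    d_ba = directed_hausdorff(cloud_b.points, cloud_a.points)[0]
    return float(max(d_ab, d_ba))
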