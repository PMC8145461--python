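"""Distributions of the switching process and convergence diagnostics.

The per-step dynamics induces the transition probability
``P(x, B) = p0(x) 1_B(S0 x) + p1(x) 1_B(S1 x)`` and with it two adjoint
operators: the Markov operator ``T`` acting on bounded test functions,
``(Tf)(x) = p0(x) f(S0 x) + p1(x) f(S1 x)``, and the push-forward ``F``
acting on probability measures, ``(F nu)(B) = integral P(x, B) dnu(x)``.
For a finitely supported measure, ``F`` splits every atom into its two map
images with weights given by the place-dependent probabilities — so n-fold
push-forwards of a point mass enumerate the 2^n composition words exactly.

Under Hölder-continuous choice probabilities bounded away from zero the
process has a unique attracting invariant measure; its support is the IFS
attractor.  Since no closed form is available, the module estimates the
measure by long-run occupation statistics and offers two empirical
diagnostics: the energy distance between estimates launched from different
initial conditions (convergence in distribution) and the nearest-neighbor
distance from orbit points to an attractor sample (support attraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .maps import AffineMapPair, PointCloud
from .switching import Trajectory

__all__ = [
    "EmpiricalMeasure",
    "markov_operator_T",
    "pushforward_F",
    "estimate_invariant_measure",
    "energy_distance",
    "distance_to_attractor",
]


@dataclass
class EmpiricalMeasure:
    """A finitely supported probability measure on R^3."""

    atoms: np.ndarray  # (n, 3) support points
    weights: np.ndarray  # (n,) positive, summing to 1

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.atoms.shape[1] != 3:
            raise ValueError(f"atoms must be (n, 3), got {self.atoms.shape}")
        if self.weights.shape != (len(self.atoms),):
            raise ValueError("weights must have one entry per atom")
        if len(self.atoms) == 0:
            raise ValueError("measure must have at least one atom")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        self.weights = self.weights / total

    @classmethod
    def point_mass(cls, x) -> "EmpiricalMeasure":
        return cls(atoms=np.asarray(x, dtype=float).reshape(1, 3), weights=np.array([1.0]))

    @classmethod
    def from_points(cls, points) -> "EmpiricalMeasure":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return cls(atoms=pts, weights=np.full(len(pts), 1.0 / len(pts)))

    def integrate(self, f: Callable[[np.ndarray], float]) -> float:
        return float(sum(w * f(x) for x, w in zip(self.atoms, self.weights)))


def markov_operator_T(ppair, pair: AffineMapPair, f: Callable, x) -> float:
    """``(Tf)(x) = p0(x) f(S0 x) + p1(x) f(S1 x)``.

    Linear in ``f`` and preserves constants; with ``f`` an indicator it
    returns the transition probability ``P(x, B)``.
    """
    x = np.asarray(x, dtype=float)
    p0, p1 = ppair.probs(x, 0)
    return p0 * float(f(pair.apply(0, x))) + p1 * float(f(pair.apply(1, x)))


def pushforward_F(
    ppair,
    pair: AffineMapPair,
    nu: EmpiricalMeasure,
    prune_threshold: float = 1e-12,
) -> EmpiricalMeasure:
    """One-step push-forward of a finitely supported measure.

    Every atom ``(x, w)`` splits into ``(S0 x, w p0(x))`` and
    ``(S1 x, w p1(x))``.  Atoms whose weight falls below
    ``prune_threshold`` (a fraction of total mass) are dropped and the
    measure renormalized; pass ``prune_threshold=0`` for the exact
    word-enumeration semantics.  Mass is conserved before pruning, so the
    duality ``integral f d(F nu) = integral (Tf) d nu`` is exact.
    """
    probs = np.array([ppair.probs(x, 0) for x in nu.atoms])
    atoms = np.vstack([pair.apply(0, nu.atoms), pair.apply(1, nu.atoms)])
    weights = np.concatenate([nu.weights * probs[:, 0], nu.weights * probs[:, 1]])
    keep = weights > prune_threshold
    if not np.any(keep):
        raise ValueError("pruning removed all atoms; lower prune_threshold")
    atoms, weights = atoms[keep], weights[keep]
    return EmpiricalMeasure(atoms=atoms, weights=weights / weights.sum())


def estimate_invariant_measure(
    simulate: Callable[..., Trajectory],
    n_steps: int,
    burn_in: int = 1000,
    seed: int = 0,
) -> EmpiricalMeasure:
    """Equal-weight occupation measure of a post-burn-in simulated orbit.

    ``simulate`` must accept ``(n_steps, rng)`` and return a
    :class:`~ifsgene.switching.Trajectory`; by the attracting-invariant-
    measure property the estimate converges in distribution as
    ``n_steps`` grows, regardless of the initial condition.
    """
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    traj = simulate(n_steps, np.random.default_rng(seed))
    return EmpiricalMeasure.from_points(traj.states[burn_in + 1 :])


def _weighted_mean_dist(
    a: np.ndarray, wa: np.ndarray, b: np.ndarray, wb: np.ndarray
) -> float:
    """``sum_ij wa_i wb_j |a_i - b_j|``, chunked to bound memory."""
    chunk = max(1, int(2e7 / max(len(b), 1)))
    total = 0.0
    for s in range(0, len(a), chunk):
        d = cdist(a[s : s + chunk], b)
        total += float(wa[s : s + chunk] @ d @ wb)
    return total


def energy_distance(mu: EmpiricalMeasure, nu: EmpiricalMeasure) -> float:
    """Energy distance ``2 E|X-Y| - E|X-X'| - E|Y-Y'|`` between two measures.

    The unhalved convention is used, so two point masses at ``x`` and ``y``
    are at distance ``2 |x - y|``.  Nonnegative, symmetric, zero iff the
    measures coincide; it metrizes convergence in distribution on the
    bounded sets the dynamics lives on.
    """
    cross = _weighted_mean_dist(mu.atoms, mu.weights, nu.atoms, nu.weights)
    within_mu = _weighted_mean_dist(mu.atoms, mu.weights, mu.atoms, mu.weights)
    within_nu = _weighted_mean_dist(nu.atoms, nu.weights, nu.atoms, nu.weights)
    return 2.0 * cross - within_mu - within_nu


def distance_to_attractor(points, reference: PointCloud) -> np.ndarray:
    """Per-point Euclidean nearest-neighbor distance to a reference cloud.

    ``points`` may be a trajectory's state array (in the same coordinate
    system as the reference cloud) or any (n, 3) array.  The sequence
    decays to the cloud-resolution floor for orbits attracted to the set.
    """
    if len(reference) == 0:
        raise ValueError("reference cloud must be nonempty")
    tree = cKDTree(reference.points)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, _ = tree.query(pts, workers=-1)
    return dist
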