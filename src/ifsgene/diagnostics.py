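"""Empirical convergence and invariance diagnostics.

None of these are proofs; they are the numerical checks that a configured
process behaves as the asymptotic theory predicts: convergence in
distribution to a unique invariant measure (checked through the energy
distance between occupation measures started far apart), attraction of
orbits to the IFS attractor (nearest-neighbor distance decay), the uniform
lower bound on the choice probabilities the uniqueness result assumes, and
the exponential-in-time bound on the expected number of gene switches.
"""

from __future__ import annotations

import math

import numpy as np

from .attractor import AttractorSpec, attractor_cloud, membership
from .config import RunConfig, run_simulation
from .maps import AffineMapPair
from .measure import EmpiricalMeasure, energy_distance
from .model import KineticParams, fixed_point_w
from .switching import IntensityPair, simulate_jump_process

__all__ = [
    "convergence_diagnostic",
    "attractor_diagnostic",
    "probability_bound_diagnostic",
    "jump_count_diagnostic",
    "run_all",
]


def convergence_diagnostic(
    config: RunConfig,
    sample_sizes: tuple[int, ...] = (100, 1000, 10_000),
    seed: int = 0,
) -> dict:
    """Energy distance between occupation measures from two distant starts.

    One orbit starts at the configured initial state shifted to the origin,
    the other at the opposite box corner (the active-gene steady state ``w``,
    or the map fixed point ``v`` for reduced-only models).  For each sample
    size ``n`` the first ``n`` post-start points of each orbit form an
    empirical measure; if the process converges in distribution to a unique
    measure the distance must decay with ``n``.  Passes when the sequence is
    strictly decreasing.
    """
    params = config.model_params()
    far = params.fixed_point(1) if isinstance(params, AffineMapPair) else fixed_point_w(params)
    n_max = max(sample_sizes)
    traj_a = _run_from(config, [0.0, 0.0, 0.0], n_max, seed)
    traj_b = _run_from(config, list(far), n_max, seed + 1)
    distances = []
    for n in sample_sizes:
        mu = EmpiricalMeasure.from_points(traj_a.states[1 : n + 1])
        nu = EmpiricalMeasure.from_points(traj_b.states[1 : n + 1])
        distances.append(energy_distance(mu, nu))
    decreasing = all(d1 > d2 for d1, d2 in zip(distances, distances[1:]))
    return {
        "sample_sizes": list(sample_sizes),
        "energy_distances": distances,
        "passed": bool(decreasing),
    }


def _run_from(config: RunConfig, start: list[float], steps: int, seed: int):
    cfg = RunConfig.from_dict({**config.to_dict(), "initial_state": start})
    return run_simulation(cfg, steps=steps, seed=seed)


def attractor_diagnostic(
    config: RunConfig,
    n_steps: int = 20_000,
    n_per_axis: int = 101,
    seed: int = 0,
    tail_fraction: float = 0.1,
    threshold: float = 10.0,
) -> dict:
    """Distance from a reduced-coordinate orbit to the attractor sample.

    Simulates the configured process in reduced coordinates and measures
    the grid-spacing-scaled nearest-neighbor distance of every orbit point
    to the parametric attractor cloud.  Passes when the supremum over the
    last ``tail_fraction`` of the orbit is below ``threshold`` grid units.
    """
    cfg_dict = config.to_dict()
    if cfg_dict["kinetic"] is not None:
        reduced = config.reduced_params()
        cfg_dict.update(
            kinetic=None, reduced=reduced.as_dict(), coords="reduced",
            initial_state=[0.0, 0.0, 0.0],
        )
        cfg = RunConfig.from_dict(cfg_dict)
    else:
        cfg, reduced = config, config.reduced_params()
    traj = run_simulation(cfg, steps=n_steps, seed=seed)
    spec = AttractorSpec(reduced=reduced)
    reference = attractor_cloud(spec, n_per_axis=n_per_axis)
    _, dist = membership(spec, traj.states, reference=reference)
    tail = dist[int((1 - tail_fraction) * len(dist)) :]
    return {
        "n_steps": n_steps,
        "n_per_axis": n_per_axis,
        "tail_sup_distance_grid_units": float(tail.max()),
        "threshold_grid_units": threshold,
        "passed": bool(tail.max() < threshold),
    }


def probability_bound_diagnostic(config: RunConfig, n_sample: int = 1024) -> dict:
    """Empirical check of the uniform lower bound on the choice probabilities.

    Samples the invariant box (or the attractor bounding box for
    reduced-only models) and reports the smallest observed ``p0`` and
    ``p1``.  A zero minimum means the uniqueness hypothesis fails — e.g.
    a degenerate run that always picks one map.
    """
    if config.semantics != "per-step":
        return {"applicable": False}
    ppair = config.probability_pair()
    upper = config.box_upper()
    if upper is None:
        spec = AttractorSpec(reduced=config.reduced_params())
        corners = np.vstack([np.zeros(3), spec.v])
        lo, hi = corners.min(axis=0), corners.max(axis=0)
    else:
        lo, hi = np.zeros(3), upper
    rng = np.random.default_rng(0)
    pts = lo + (hi - lo) * rng.random((n_sample, 3))
    vals = np.array([ppair.probs(p, 0) for p in pts])
    min_p = float(vals.min())
    claimed = config.delta0
    return {
        "applicable": True,
        "min_p0": float(vals[:, 0].min()),
        "min_p1": float(vals[:, 1].min()),
        "claimed_delta0": claimed,
        "passed": bool(min_p > 0 and (claimed is None or min_p >= claimed)),
    }


def jump_count_diagnostic(
    params: KineticParams,
    qpair: IntensityPair,
    t: float = 20.0,
    n_runs: int = 1000,
    seed: int = 0,
    init_state=(0.0, 0.0, 0.0),
    init_gene: int = 0,
) -> dict:
    """Empirical mean number of switches by time ``t`` against ``exp(q_max t)``.

    The expected jump count admits the crude geometric-series bound
    ``E[N_t] <= exp(q_max t)``; the diagnostic reports the Monte-Carlo mean
    with its standard error and passes when mean minus three standard
    errors stays below the bound.
    """
    rng = np.random.default_rng(seed)
    horizon = int(math.ceil(t / params.delta))
    counts = np.empty(n_runs)
    for k in range(n_runs):
        traj = simulate_jump_process(params, qpair, init_state, init_gene, horizon, rng)
        counts[k] = traj.n_jumps_by(t)
    bound = math.exp(qpair.q_max * t) if qpair.q_max is not None else float("inf")
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else float("nan")
    return {
        "t": t,
        "n_runs": n_runs,
        "mean_jumps": mean,
        "sem_jumps": sem,
        "bound_exp_qmax_t": bound,
        "passed": bool(mean - 3 * sem <= bound),
    }


def run_all(
    config: RunConfig,
    sample_sizes: tuple[int, ...] = (100, 1000, 10_000),
    seed: int = 0,
) -> dict:
    """The full diagnostic report a `diagnose` run emits."""
    report = {
        "config": config.to_dict(),
        "convergence": convergence_diagnostic(config, sample_sizes, seed=seed),
        "probability_bound": probability_bound_diagnostic(config),
        "attractor": attractor_diagnostic(config, seed=seed),
    }
    if config.q0 is not None and config.q1 is not None:
        kin = config.model_params()
        if isinstance(kin, KineticParams):
            report["jump_count"] = jump_count_diagnostic(
                kin, config.intensity_pair(), seed=seed,
                init_state=config.initial_state, init_gene=config.initial_gene,
            )
    checks = [v for v in report.values() if isinstance(v, dict) and "passed" in v]
    report["all_passed"] = bool(all(v["passed"] for v in checks))
    return report
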