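"""Stochastic gene switching: life-span law, jump sampling, and simulators.

Two switching semantics are implemented side by side, both first-class:

* **Per-step place-dependent probabilities** (:func:`simulate_ifs_process`):
  at every step the gene state for the next step is drawn with probabilities
  ``p0(x), p1(x)`` evaluated at the current molecule state ``x``, and the
  corresponding one-step map is applied.  The draw does not depend on the
  current gene state.  This is the iterated-function-system picture used for
  the invariant-measure results.

* **Intensity-driven jump times** (:func:`simulate_jump_process`): the gene
  stays in state ``i`` for a random number of steps whose law is set by the
  discrete life-span function

  ``Phi(t) = exp(-sum_{s=0}^{floor(t)-1} q_i(pi_i(s, x0)))``,

  the discrete analogue of the exponential-of-integrated-hazard survival law
  of piecewise deterministic Markov processes; at the sampled jump time the
  gene flips and the flow restarts from the endpoint.

The two pictures are linked by :func:`switch_rule_from_intensities`, which
turns a pair of intensities into the exact per-step rule "switch away from
``i`` with probability ``q_i(x)``" implied by the telescoping identity
``Phi(t+1)/Phi(t) = 1 - q(pi(t, x0))`` of the exact product form.  Note the
bridged rule depends on the current gene state whenever ``q0 != q1``,
whereas the per-step semantics above is gene-state independent; the two
agree in law exactly for the product survival form and to first order in
``q`` for the exponential form.

Time is measured in integer step units throughout; physical time is
``step * delta``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import qmc

from .functions import StateFunction, function_spec
from .model import KineticParams, fixed_point_w, step

__all__ = [
    "IntensityPair",
    "ProbabilityPair",
    "BridgedSwitchRule",
    "Trajectory",
    "JumpCapExceededError",
    "life_span",
    "survival_product",
    "jump_cdf",
    "sample_jump_time",
    "simulate_jump_process",
    "simulate_ifs_process",
    "switch_rule_from_intensities",
]


def _sobol_box_sample(box_upper: np.ndarray, n: int = 1024, seed: int = 0) -> np.ndarray:
    sampler = qmc.Sobol(d=3, scramble=True, seed=seed)
    return sampler.random(n) * box_upper


@dataclass
class IntensityPair:
    """Jump intensities ``q0, q1`` (hazard of leaving gene state 0 resp. 1).

    Both must be positive and bounded.  If ``box_upper`` is given, the
    claimed bound ``q_max`` (and positivity) is checked empirically on a
    Sobol sample of the box ``[0, box_upper]``; violations raise a warning,
    not an error.  When ``q_max`` is omitted it is estimated as the sample
    supremum (with a 5% safety margin).
    """

    q0: StateFunction
    q1: StateFunction
    q_max: float | None = None
    box_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.box_upper is not None:
            pts = _sobol_box_sample(np.asarray(self.box_upper, dtype=float))
            vals = np.array([[self.q0(p), self.q1(p)] for p in pts])
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                warnings.warn(
                    "intensity functions are not strictly positive and finite "
                    "on the sampled invariant box",
                    stacklevel=2,
                )
            observed = float(vals.max())
            if self.q_max is None:
                self.q_max = 1.05 * observed
            elif observed > self.q_max:
                warnings.warn(
                    f"claimed q_max={self.q_max} exceeded on the sampled box "
                    f"(observed {observed:.6g})",
                    stacklevel=2,
                )

    def q(self, i: int) -> StateFunction:
        if i not in (0, 1):
            raise ValueError(f"gene state must be 0 or 1, got {i!r}")
        return self.q0 if i == 0 else self.q1

    def spec(self) -> dict:
        return {"q0": function_spec(self.q0), "q1": function_spec(self.q1), "q_max": self.q_max}


@dataclass
class ProbabilityPair:
    """Place-dependent map-choice probabilities ``p0(x), p1(x)``.

    ``p1`` defaults to ``1 - p0``.  ``delta0`` is the claimed uniform lower
    bound on both probabilities (the hypothesis guaranteeing a unique
    attracting invariant measure); if ``box_upper`` is given, normalization
    and the bound are spot-checked on a Sobol sample of the box and
    violations raise a warning.
    """

    p0: StateFunction
    p1: StateFunction | None = None
    delta0: float | None = None
    box_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.p1 is None:
            base = self.p0

            def complement(x, _base=base) -> float:
                return 1.0 - _base(x)

            complement.spec = {"name": "complement_of_p0"}  # type: ignore[attr-defined]
            self.p1 = complement
        if self.box_upper is not None:
            pts = _sobol_box_sample(np.asarray(self.box_upper, dtype=float))
            vals = np.array([[self.p0(p), self.p1(p)] for p in pts])
            if np.max(np.abs(vals.sum(axis=1) - 1.0)) > 1e-12:
                warnings.warn("p0 + p1 deviates from 1 on the sampled box", stacklevel=2)
            if np.any(vals < 0) or np.any(vals > 1):
                warnings.warn("probabilities leave [0, 1] on the sampled box", stacklevel=2)
            if self.delta0 is not None and float(vals.min()) < self.delta0:
                warnings.warn(
                    f"claimed lower bound delta0={self.delta0} violated on the "
                    f"sampled box (observed min {vals.min():.6g})",
                    stacklevel=2,
                )

    @property
    def gene_state_dependent(self) -> bool:
        return False

    def probs(self, x, i: int) -> tuple[float, float]:
        """Choice probabilities ``(p0, p1)`` at ``x``; independent of ``i``."""
        p0 = float(self.p0(x))
        p1 = float(self.p1(x))
        if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
            raise ValueError(f"probabilities ({p0}, {p1}) outside [0, 1] at x={x!r}")
        return p0, p1

    def spec(self) -> dict:
        return {
            "p0": function_spec(self.p0),
            "p1": function_spec(self.p1),
            "delta0": self.delta0,
            "gene_state_dependent": self.gene_state_dependent,
        }


@dataclass
class BridgedSwitchRule:
    """Per-step switch rule derived from intensities: leave ``i`` w.p. ``q_i(x)``.

    This is the exact one-step law of the product-form survival function.
    Unlike :class:`ProbabilityPair`, the implied choice probabilities depend
    on the current gene state whenever ``q0`` and ``q1`` differ; the
    ``gene_state_dependent`` flag records whether they do (decided on a
    sample of evaluation points).
    """

    intensities: IntensityPair
    gene_state_dependent: bool = field(default=False)

    def probs(self, x, i: int) -> tuple[float, float]:
        q = float(self.intensities.q(i)(x))
        if not 0.0 < q < 1.0:
            raise ValueError(
                f"bridged switch rule needs 0 < q_i(x) < 1, got {q!r} at x={x!r}"
            )
        p_stay, p_leave = 1.0 - q, q
        return (p_stay, p_leave) if i == 0 else (p_leave, p_stay)

    def spec(self) -> dict:
        return {
            "bridge": "per-step switch probability q_i(x)",
            "gene_state_dependent": self.gene_state_dependent,
            **self.intensities.spec(),
        }


def switch_rule_from_intensities(
    qpair: IntensityPair, probe_points: np.ndarray | None = None
) -> BridgedSwitchRule:
    """Exact per-step bridge between intensity- and probability-driven switching.

    The product survival form telescopes as
    ``Phi(t+1)/Phi(t) = 1 - q(pi(t, x0))``, i.e. the gene leaves state ``i``
    at each step independently with probability ``q_i`` at the current
    point.  The returned rule reproduces the product-form jump-time law
    exactly; it matches the exponential life-span law to first order in
    ``q``.  When ``q0 != q1`` the rule is gene-state dependent, which the
    per-step IFS semantics (by construction gene-state independent) cannot
    express; the flag in the rule records this.
    """
    if probe_points is None:
        probe_points = _sobol_box_sample(np.ones(3), n=64)
    v0 = np.array([qpair.q0(p) for p in probe_points])
    v1 = np.array([qpair.q1(p) for p in probe_points])
    dependent = bool(np.max(np.abs(v0 - v1)) > 1e-12)
    return BridgedSwitchRule(intensities=qpair, gene_state_dependent=dependent)


# ---------------------------------------------------------------------------
# life-span / jump-time machinery
# ---------------------------------------------------------------------------


def _hazards_along_orbit(
    q: StateFunction, params: KineticParams, i: int, x0, n: int
) -> np.ndarray:
    """Evaluate q along the first n points of the constant-i orbit (step units)."""
    x = np.asarray(x0, dtype=float)
    out = np.empty(n)
    for s in range(n):
        val = float(q(x))
        if not math.isfinite(val):
            raise ValueError(f"intensity evaluated to non-finite value {val!r}")
        out[s] = val
        x = step(params, x, i)
    return out


def life_span(q: StateFunction, params: KineticParams, i: int, x0, t: float) -> float:
    """Survival probability ``Phi(t) = exp(-sum_{s=0}^{floor(t)-1} q(pi_i(s, x0)))``.

    ``t`` is in step units; the empty sum gives ``Phi = 1`` for ``t < 1``.
    Nonincreasing in ``t`` and strictly positive for bounded ``q``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    n = int(math.floor(t))
    if n == 0:
        return 1.0
    return float(math.exp(-_hazards_along_orbit(q, params, i, x0, n).sum()))


def survival_product(q: StateFunction, params: KineticParams, i: int, x0, t: float) -> float:
    """Exact product-form survival ``prod_{s=0}^{floor(t)-1} (1 - q(pi_i(s, x0)))``.

    Requires ``q < 1`` along the orbit.  Agrees with :func:`life_span` to
    first order for small ``q``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    n = int(math.floor(t))
    if n == 0:
        return 1.0
    hazards = _hazards_along_orbit(q, params, i, x0, n)
    if np.any(hazards >= 1.0):
        raise ValueError("survival product undefined: q >= 1 along the orbit")
    return float(np.prod(1.0 - hazards))


def jump_cdf(q: StateFunction, params: KineticParams, i: int, x0, t: float) -> float:
    """Jump-time distribution ``F(t) = 1 - Phi(t)``; a step function of floor(t)."""
    return 1.0 - life_span(q, params, i, x0, t)


class JumpCapExceededError(RuntimeError):
    """No jump occurred within ``t_cap`` steps; carries the residual survival."""

    def __init__(self, t_cap: int, phi_at_cap: float):
        super().__init__(
            f"no gene switch within {t_cap} steps (survival Phi(t_cap) = {phi_at_cap:.3e})"
        )
        self.t_cap = t_cap
        self.phi_at_cap = phi_at_cap


def sample_jump_time(
    q: StateFunction,
    params: KineticParams,
    i: int,
    x0,
    rng: np.random.Generator,
    t_cap: int = 10**6,
) -> int:
    """Sample the first switch time (in steps) by exact inverse-CDF search.

    Returns the smallest integer ``n >= 1`` with ``F(n) >= U`` for a uniform
    draw ``U``, i.e. ``P(t1 > n) = Phi(n)``; the hazard sum is accumulated
    along the orbit until it crosses ``-log(1 - U)``.  The jump time is
    always at least one step.
    """
    if t_cap < 1:
        raise ValueError("t_cap must be >= 1")
    u = rng.random()
    threshold = -math.log1p(-u)
    total = 0.0
    x = np.asarray(x0, dtype=float)
    for n in range(1, t_cap + 1):
        val = float(q(x))
        if not math.isfinite(val):
            raise ValueError(f"intensity evaluated to non-finite value {val!r}")
        total += val
        if total >= threshold:
            return n
        x = step(params, x, i)
    raise JumpCapExceededError(t_cap, math.exp(-total))


# ---------------------------------------------------------------------------
# trajectories and the two simulators
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A simulated hybrid orbit: molecule states plus the binary gene state.

    ``states[n]`` and ``gene[n]`` describe the process at step ``n``
    (physical time ``n * delta``); ``jump_steps`` lists the steps at which
    the gene state flipped (the gene index already carries the new value at
    the flip step).
    """

    states: np.ndarray  # (n_steps + 1, 3)
    gene: np.ndarray  # (n_steps + 1,) in {0, 1}
    delta: float
    jump_steps: np.ndarray  # strictly increasing step indices
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.gene = np.asarray(self.gene, dtype=int)
        self.jump_steps = np.asarray(self.jump_steps, dtype=int)
        if len(self.states) != len(self.gene):
            raise ValueError("states and gene must have equal length")
        if np.any(np.diff(self.jump_steps) <= 0):
            raise ValueError("jump steps must be strictly increasing")

    @property
    def steps(self) -> np.ndarray:
        return np.arange(len(self.states))

    @property
    def times(self) -> np.ndarray:
        return self.steps * self.delta

    @property
    def jump_times(self) -> np.ndarray:
        return self.jump_steps * self.delta

    def n_jumps_by(self, t: float) -> int:
        """Number of switches strictly before physical time ``t``."""
        return int(np.sum(self.jump_times < t))

    def __len__(self) -> int:
        return len(self.states)


def simulate_jump_process(
    params: KineticParams,
    qpair: IntensityPair,
    init_state,
    init_gene: int,
    horizon: int,
    rng: np.random.Generator,
    t_cap: int = 10**6,
) -> Trajectory:
    """Simulate the intensity-driven process for ``horizon`` steps.

    Alternates deterministic constant-gene segments with switches at jump
    times sampled from the life-span law.  At a jump step the molecule state
    is the flow endpoint of the finished segment while the gene index
    already carries the flipped value; the next molecule update uses the
    pre-switch gene state (updates always use the gene state of the step
    being left).
    """
    if init_gene not in (0, 1):
        raise ValueError("init_gene must be 0 or 1")
    x = np.asarray(init_state, dtype=float)
    states = np.empty((horizon + 1, 3))
    gene = np.empty(horizon + 1, dtype=int)
    states[0], gene[0] = x, init_gene
    jump_steps: list[int] = []

    n = 0
    i = init_gene
    while n < horizon:
        # a jump beyond the remaining horizon is simply "no jump this run":
        # the inverse-CDF search is capped at the steps actually simulated
        try:
            t1 = sample_jump_time(
                qpair.q(i), params, i, x, rng, t_cap=min(t_cap, horizon - n)
            )
        except JumpCapExceededError:
            t1 = None
        seg = (horizon - n) if t1 is None else t1
        for k in range(seg):
            x = step(params, x, i)
            states[n + 1 + k] = x
            gene[n + 1 + k] = i
        n += seg
        if t1 is not None:  # the switch happened inside the horizon
            gene[n] = 1 - i
            i = 1 - i
            jump_steps.append(n)
    return Trajectory(
        states=states,
        gene=gene,
        delta=params.delta,
        jump_steps=np.array(jump_steps, dtype=int),
        meta={"semantics": "intensity", "params": params.as_dict(), **qpair.spec()},
    )


def simulate_ifs_process(
    params,
    ppair,
    init_state,
    init_gene: int,
    n_steps: int,
    rng: np.random.Generator,
    coords: str = "original",
) -> Trajectory:
    """Simulate the per-step place-dependent process for ``n_steps`` steps.

    At each step the next gene state ``j`` is drawn with probabilities
    ``ppair.probs(x, i)`` evaluated at the *current* point, then the one-step
    map with gene state ``j`` is applied — the one-step map ``S_j`` of the
    reduced system when ``coords='reduced'``, the original-coordinate kinetic
    step otherwise.  ``params`` may be a :class:`~ifsgene.model.KineticParams`
    or, for reduced-coordinate runs only, a bare
    :class:`~ifsgene.maps.AffineMapPair`.  ``ppair`` may be a
    :class:`ProbabilityPair` (gene-state independent) or a
    :class:`BridgedSwitchRule`.
    """
    from .maps import AffineMapPair

    if init_gene not in (0, 1):
        raise ValueError("init_gene must be 0 or 1")
    if coords not in ("original", "reduced"):
        raise ValueError("coords must be 'original' or 'reduced'")
    if isinstance(params, AffineMapPair):
        if coords != "reduced":
            raise ValueError("a bare map pair supports only reduced coordinates")
        pair, delta, params_dict = params, 1.0, params.reduced.as_dict()
        advance = lambda x, j: pair.apply(j, x)  # noqa: E731
    elif coords == "reduced":
        pair = AffineMapPair.from_kinetic(params)
        delta, params_dict = params.delta, params.as_dict()
        advance = lambda x, j: pair.apply(j, x)  # noqa: E731
    else:
        delta, params_dict = params.delta, params.as_dict()
        advance = lambda x, j: step(params, x, j)  # noqa: E731

    x = np.asarray(init_state, dtype=float)
    states = np.empty((n_steps + 1, 3))
    gene = np.empty(n_steps + 1, dtype=int)
    states[0], gene[0] = x, init_gene
    jump_steps: list[int] = []
    i = init_gene
    uniforms = rng.random(n_steps)
    for n in range(n_steps):
        p0, _ = ppair.probs(x, i)
        j = 0 if uniforms[n] < p0 else 1
        x = advance(x, j)
        states[n + 1] = x
        gene[n + 1] = j
        if j != i:
            jump_steps.append(n + 1)
        i = j
    return Trajectory(
        states=states,
        gene=gene,
        delta=delta,
        jump_steps=np.array(jump_steps, dtype=int),
        meta={
            "semantics": "per-step",
            "coords": coords,
            "params": params_dict,
            **ppair.spec(),
        },
    )


def invariant_box_upper(params: KineticParams) -> np.ndarray:
    """Upper corner ``w`` of the invariant box ``[0, w1] x [0, w2] x [0, w3]``."""
    return fixed_point_w(params)
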