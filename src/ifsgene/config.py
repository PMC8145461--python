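"""Run configuration: a single YAML document describing one reproducible run.

A configuration names the model (kinetic rates or bare retention factors —
exactly one of the two), the switching semantics (``per-step`` probabilities
or ``intensity``-driven jump times), the probability/intensity function
specs, the initial hybrid state, the horizon and the RNG seed.  Every
stochastic command is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .functions import resolve_function
from .maps import AffineMapPair
from .model import KineticParams, ReducedParams, fixed_point_w, reduce_params
from .switching import (
    IntensityPair,
    ProbabilityPair,
    Trajectory,
    simulate_ifs_process,
    simulate_jump_process,
)

__all__ = ["RunConfig", "load_config", "run_simulation"]


@dataclass
class RunConfig:
    name: str = "run"
    kinetic: dict | None = None
    reduced: dict | None = None
    semantics: str = "per-step"
    coords: str = "original"
    p0: object | None = None
    p1: object | None = None
    q0: object | None = None
    q1: object | None = None
    delta0: float | None = None
    initial_state: list[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    initial_gene: int = 0
    steps: int = 1000
    seed: int | None = None
    attractor: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.kinetic is None) == (self.reduced is None):
            raise ValueError("exactly one of 'kinetic' and 'reduced' must be given")
        if self.semantics not in ("per-step", "intensity"):
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.coords not in ("original", "reduced"):
            raise ValueError(f"unknown coordinate system {self.coords!r}")
        if self.reduced is not None and self.coords != "reduced":
            raise ValueError("a reduced-only model supports only reduced coordinates")
        if self.reduced is not None and self.semantics != "per-step":
            raise ValueError("intensity semantics needs the kinetic parameter block")
        if self.initial_gene not in (0, 1):
            raise ValueError("initial_gene must be 0 or 1")
        if self.semantics == "per-step" and self.p0 is None:
            raise ValueError("per-step semantics requires a p0 spec")
        if self.semantics == "intensity" and (self.q0 is None or self.q1 is None):
            raise ValueError("intensity semantics requires q0 and q1 specs")
        # materialize early so bad blocks fail at load time
        self.model_params()

    # -- builders ----------------------------------------------------------

    def model_params(self) -> KineticParams | AffineMapPair:
        if self.kinetic is not None:
            return KineticParams(**self.kinetic)
        return AffineMapPair(reduced=ReducedParams(**self.reduced))

    def reduced_params(self) -> ReducedParams:
        params = self.model_params()
        if isinstance(params, AffineMapPair):
            return params.reduced
        return reduce_params(params)

    def box_upper(self) -> np.ndarray | None:
        params = self.model_params()
        if isinstance(params, KineticParams):
            return fixed_point_w(params)
        return None

    def probability_pair(self) -> ProbabilityPair:
        return ProbabilityPair(
            p0=resolve_function(self.p0),
            p1=None if self.p1 is None else resolve_function(self.p1),
            delta0=self.delta0,
            box_upper=self.box_upper(),
        )

    def intensity_pair(self) -> IntensityPair:
        return IntensityPair(
            q0=resolve_function(self.q0),
            q1=resolve_function(self.q1),
            box_upper=self.box_upper(),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return RunConfig.from_dict(data)


def run_simulation(
    config: RunConfig,
    steps: int | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Execute the simulation a config describes; pure in (config, seed)."""
    n_steps = config.steps if steps is None else steps
    run_seed = config.seed if seed is None else seed
    if run_seed is None:
        raise ValueError("a seed is mandatory for stochastic runs")
    rng = np.random.default_rng(run_seed)
    params = config.model_params()
    if config.semantics == "per-step":
        traj = simulate_ifs_process(
            params,
            config.probability_pair(),
            config.initial_state,
            config.initial_gene,
            n_steps,
            rng,
            coords=config.coords,
        )
    else:
        traj = simulate_jump_process(
            params,
            config.intensity_pair(),
            config.initial_state,
            config.initial_gene,
            n_steps,
            rng,
        )
    traj.meta.update({"config_name": config.name, "seed": run_seed})
    return traj
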