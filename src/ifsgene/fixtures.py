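"""Canonical parameter sets and seeded reference runs.

Three named configurations recur throughout the package and its tests:

* ``gene-off`` — the worked kinetic example ``delta=1, R=1, mu_PR=1/4,
  C=mu_R=1/4, P=mu_P=1/3`` with the gene held off; its closed-form solution
  has geometric ratios (1/2, 3/4, 2/3) and active-gene steady state (2,2,2).
* ``chaos-game`` — the chaos game on the reduced system with retention factors
  (1/2, 3/4, 2/3), constant choice probabilities 1/2, seed point at the
  origin, 100,000 iterations.
* ``feedback`` — the stochastic simulation of the full kinetic system with the
  place-dependent gene-off probability ``p0(x) = 1/(2(1+|x|^2))`` and
  initial state (1/2, 1/2, 1/2).
"""

from __future__ import annotations

from pathlib import Path

from .config import RunConfig, run_simulation
from .io import write_trajectory

__all__ = ["fixture", "fixture_names", "generate_fixtures"]

_EXAMPLE1_KINETIC = {
    "R": 1.0,
    "C": 0.25,
    "P": 1.0 / 3.0,
    "mu_PR": 0.25,
    "mu_R": 0.25,
    "mu_P": 1.0 / 3.0,
    "delta": 1.0,
}


def _gene_off() -> RunConfig:
    return RunConfig(
        name="gene-off",
        kinetic=dict(_EXAMPLE1_KINETIC),
        semantics="per-step",
        coords="original",
        p0={"name": "constant", "value": 1.0},  # gene held off
        initial_state=[1.0, 1.0, 1.0],
        initial_gene=0,
        steps=100,
        seed=0,
    )


def _chaos_game() -> RunConfig:
    return RunConfig(
        name="chaos-game",
        reduced={"a": 0.5, "b": 0.75, "c": 2.0 / 3.0},
        semantics="per-step",
        coords="reduced",
        p0={"name": "constant", "value": 0.5},
        initial_state=[0.0, 0.0, 0.0],
        initial_gene=0,
        steps=100_000,
        seed=0,
    )


def _feedback() -> RunConfig:
    return RunConfig(
        name="feedback",
        kinetic=dict(_EXAMPLE1_KINETIC),
        semantics="per-step",
        coords="original",
        p0={"name": "inverse_quadratic", "scale": 0.5},
        initial_state=[0.5, 0.5, 0.5],
        initial_gene=0,
        steps=10_000,
        seed=0,
    )


_FIXTURES = {"gene-off": _gene_off, "chaos-game": _chaos_game, "feedback": _feedback}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str) -> RunConfig:
    """A fresh :class:`~ifsgene.config.RunConfig` for a named fixture."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None


def generate_fixtures(outdir: str | Path) -> list[Path]:
    """Write every fixture config plus a short seeded reference trajectory.

    Each fixture yields ``<name>.yaml`` and a 100-step
    ``<name>.reference.csv`` (with metadata sidecar) regenerated from the
    embedded seed, so reference data is always reproducible from the config
    alone.  Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in fixture_names():
        cfg = fixture(name)
        cfg_path = outdir / f"{name}.yaml"
        cfg.save(cfg_path)
        written.append(cfg_path)
        traj = run_simulation(cfg, steps=100)
        written.extend(write_trajectory(traj, outdir / f"{name}.reference.csv"))
    return written
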