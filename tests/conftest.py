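import numpy as np
import pytest

from ifsgene import (
    EXAMPLE1,
    AffineMapPair,
    AttractorSpec,
    KineticParams,
    ReducedParams,
    reduce_params,
)


@pytest.fixture
def example1() -> KineticParams:
    """Canonical kinetic rates: retention factors (1/2, 3/4, 2/3), w = (2,2,2)."""
    return EXAMPLE1


@pytest.fixture
def reduced_canonical() -> ReducedParams:
    return ReducedParams(a=0.5, b=0.75, c=2.0 / 3.0)


@pytest.fixture
def map_pair(reduced_canonical) -> AffineMapPair:
    return AffineMapPair(reduced=reduced_canonical)


@pytest.fixture
def attractor_spec(reduced_canonical) -> AttractorSpec:
    return AttractorSpec(reduced=reduced_canonical)


def random_kinetic_params(rng: np.random.Generator) -> KineticParams:
    """A random admissible, non-degenerate parameter set."""
    while True:
        a, b, c = rng.uniform(0.05, 0.95, size=3)
        if min(abs(a - b), abs(b - c), abs(c - a)) < 1e-3:
            continue
        split = rng.uniform(0.2, 0.8)
        C = split * (1.0 - a)
        mu_PR = (1.0 - split) * (1.0 - a)
        mu_R = 1.0 - b
        P = rng.uniform(0.05, 0.95) * b  # keeps mu_R + P < 1
        mu_P = 1.0 - c
        R = rng.uniform(0.1, 5.0)
        try:
            return KineticParams(R=R, C=C, P=P, mu_PR=mu_PR, mu_R=mu_R, mu_P=mu_P)
        except ValueError:
            continue


@pytest.fixture
def param_sampler():
    return random_kinetic_params
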