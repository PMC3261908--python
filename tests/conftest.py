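import numpy as np
import pytest

from quorumlogic import (
    DEFAULT_PLF,
    NoiseModel,
    PLFParams,
    generate_plf_grid,
)


@pytest.fixture(scope="session")
def default_params() -> PLFParams:
    return DEFAULT_PLF


@pytest.fixture(scope="session")
def clean_grid():
    """Noise-free default 6x7 grid (2 replicates, identical)."""
    return generate_plf_grid(noise=NoiseModel(cv=0.0, seed=0), replicates=2)


@pytest.fixture(scope="session")
def noisy_grid():
    """Default grid with the standard cv=0.15 log-normal noise."""
    return generate_plf_grid(noise=NoiseModel(cv=0.15, seed=11), replicates=3)


def random_plf_params(rng: np.random.Generator) -> PLFParams:
    """A random valid PLF parameter set, log-uniform over broad ranges."""
    return PLFParams(
        basal_fraction=float(10 ** rng.uniform(-4, -0.7)),
        ahl_luxr_halfsat=float(10 ** rng.uniform(0, 3)),
        luxr_dna_halfsat=float(10 ** rng.uniform(0, 3)),
        hill_m=float(rng.uniform(1.0, 4.0)),
        hill_n=float(rng.uniform(0.5, 3.0)),
        ahl_density_const=float(10 ** rng.uniform(-1, 2)),
        density=float(10 ** rng.uniform(-2, 0)),
    )
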