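import numpy as np
import pytest

from inflammetry.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_pk_maps,
    generate_sources,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale cohort for fast structural tests."""
    return SimulationConfig(
        grid_dims=(14, 14, 14), n_sources=3, n_timepoints=60, seed=5
    )


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_stack_truth(default_config):
    sources = generate_sources(default_config)
    return generate_pk_maps(sources, default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
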