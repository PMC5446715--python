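import dataclasses

import numpy as np
import pytest

from smartsva import SimulationConfig, assemble_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast, small simulation configuration for unit tests."""
    base = SimulationConfig(p=800, n=60, seed=11)
    return dataclasses.replace(base, **overrides)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared across read-only tests."""
    return assemble_dataset(small_config())
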