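import dataclasses

import pytest

from mpdepth import SimulationConfig, build_stimulus_grid


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced session (3 observers, 5 blocks) for fast end-to-end tests."""
    return dataclasses.replace(SimulationConfig(), n_observers=3, n_blocks=5)


@pytest.fixture(scope="session")
def default_grid(default_config):
    return build_stimulus_grid(default_config)
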