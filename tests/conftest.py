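import numpy as np
import pytest

from phenospring import (
    SyntheticConfig,
    generate_network,
    generate_observations,
    generate_observed_climate,
)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study region: 8 stations, full observed span."""
    return SyntheticConfig(n_stations=8, seed=11)


@pytest.fixture(scope="session")
def small_network(small_config):
    return generate_network(small_config)


@pytest.fixture(scope="session")
def small_climate(small_config, small_network):
    return generate_observed_climate(small_config, small_network)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero observation noise and no missing data: predictions must
    reproduce observations exactly."""
    return SyntheticConfig(
        n_stations=6, years_observed=(1991, 2010),
        obs_noise_sd_days=0.0, missing_rate=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_data(noiseless_config):
    stations = generate_network(noiseless_config)
    climate = generate_observed_climate(noiseless_config, stations)
    observations = generate_observations(noiseless_config, stations, climate)
    return stations, climate, observations


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
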