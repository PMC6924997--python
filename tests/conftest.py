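import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iembench import FeatureSpace, SimConfig, make_cosine_basis, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def space():
    return FeatureSpace(period=180.0, grid_size=180)


@pytest.fixture(scope="session")
def cosine8(space):
    return make_cosine_basis(8, space=space)


@pytest.fixture(scope="session")
def small_config():
    """A fast noiseless simulation (few voxels/neurons) for unit tests."""
    return SimConfig(
        n_voxels=12, n_neurons_per_voxel=20, n_trials_per_cell=2, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_dataset(
        SimConfig(n_voxels=30, n_neurons_per_voxel=30, n_trials_per_cell=4,
                  noise_sd=5.0, seed=11)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
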