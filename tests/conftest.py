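import numpy as np
import pytest

from avaflow import (GroundTruth, SyntheticConfig, generate_peak_dataset,
                     generate_recordings)


@pytest.fixture(scope="session")
def truth_noise_free():
    return GroundTruth(noise_sd_ava=0.0)


@pytest.fixture(scope="session")
def truth_default():
    return GroundTruth()


@pytest.fixture(scope="session")
def small_config():
    """Reduced factorial: 2 valves x 2 grades x 3 outputs, default rates."""
    return SyntheticConfig(seed=3, n_valves=2, grades=("a", "c"),
                           cardiac_outputs=(0.5, 2.5, 5.0))


@pytest.fixture(scope="session")
def small_recordings(small_config, truth_noise_free):
    return generate_recordings(small_config, truth_noise_free)


@pytest.fixture(scope="session")
def small_analytic(small_config, truth_noise_free):
    return generate_peak_dataset(small_config, truth_noise_free)


@pytest.fixture(scope="session")
def full_noise_free_dataset(truth_noise_free):
    """Full 11x3x10 factorial with zero AVA noise."""
    return generate_peak_dataset(SyntheticConfig(seed=7), truth_noise_free)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
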