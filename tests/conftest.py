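import numpy as np
import pytest

from roldsis import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Small noiseless experiment with a 60-degree planted angle."""
    config = simulate.SyntheticConfig(
        n_features=64, n_stimuli=5, trials_per_stimulus=4,
        angle_deg=60.0, noise_sd=0.0, seed=11,
    )
    return simulate.generate(config)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Moderate-noise experiment used by bootstrap/benchmark tests."""
    config = simulate.SyntheticConfig(
        n_features=32, n_stimuli=5, trials_per_stimulus=40,
        angle_deg=60.0, snr_db=0.0, seed=7,
    )
    return simulate.generate(config)


def random_observation_set(rng, m, n, y_scale=1.0):
    X = rng.standard_normal((m, n))
    y = rng.standard_normal(m) * y_scale
    return X, y
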