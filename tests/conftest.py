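import numpy as np
import pytest

from lowrankeeg import default_spec, generate_dataset, extract_features
from lowrankeeg.synthetic import exponential_noise_cov, smooth_patterns


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_spec(seed=7, **overrides):
    """Compact study conditions: 10 channels, 20 s trials, 5 sessions."""
    defaults = dict(
        n_channels=10,
        trial_len=20.0,
        patterns=smooth_patterns(10, 2),
        noise_cov=exponential_noise_cov(10, variance=1.0, corr_length=3.0),
    )
    defaults.update(overrides)
    return default_spec(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """Ten 20 s recordings (5 sessions x 2 classes) with a beta/gamma class
    contrast; shared across tests, treated as read-only."""
    return generate_dataset(small_spec())


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Wide-band covariance features for the shared dataset."""
    return extract_features(small_dataset)


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T / n + np.eye(n))
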