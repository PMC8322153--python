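import numpy as np
import pytest

import spikepairs as sp


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def correlated_dist():
    """A single-cluster correlated pair distribution (gains 2:1)."""
    return sp.sample_pair_distribution(101, n_trials=200)


@pytest.fixture(scope="session")
def elongated_cloud():
    """Gaussian cloud with population PC1 at 30 degrees, 3:1 axis sds."""
    rng = np.random.default_rng(42)
    phi = np.deg2rad(30.0)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    cov = R @ np.diag([9.0, 1.0]) @ R.T
    return rng.multivariate_normal([20.0, 25.0], cov, size=300)
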