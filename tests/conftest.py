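import numpy as np
import pytest

from crba import CRBA, SyntheticSpec, make_synthetic


@pytest.fixture(scope="session")
def synthetic_data():
    """Default 10-cluster fixture: 5,000 samples, p=196, separable prototypes."""
    return make_synthetic(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def fitted(synthetic_data):
    """Model fitted on the default fixture (20k presentations), labeled."""
    res = CRBA(synthetic_data.X, m=10, n=1, seed=1).fit(presentations=20_000)
    res.label(synthetic_data.X, synthetic_data.y)
    return res


@pytest.fixture(scope="session")
def two_cluster_data():
    """Two clusters with disjoint supports (orthogonal prototypes)."""
    return make_synthetic(SyntheticSpec(k=2, p=40, per_class=100, separation=1.0,
                                        prototype_sparsity=0.25, noise_sd=0.02, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
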