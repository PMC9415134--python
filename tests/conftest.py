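import numpy as np
import pytest

from ospelm.network import NetworkConfig, init_batch
from ospelm.preprocessing import FeatureGrouping
from ospelm.rf import AttenuationModel, RFLinkParams, TreeScenario, generate_dataset


@pytest.fixture
def link_params():
    return RFLinkParams()


@pytest.fixture
def attenuation():
    return AttenuationModel()


@pytest.fixture
def scenario():
    return TreeScenario(mc=0.2, distance=0.5, humidity=55.0, dbh=0.2)


@pytest.fixture(scope="session")
def stream_1000():
    """One default drifting synthetic stream, shared across tests."""
    return generate_dataset(1000, rng_seed=123)


@pytest.fixture
def small_state():
    """A small initialized network on random data (seeded, reproducible)."""
    rng = np.random.default_rng(42)
    X = rng.uniform(0, 1, (60, 5))
    Y = rng.normal(0.5, 0.2, (60, 1))
    cfg = NetworkConfig(z1=4, z2=5)
    return init_batch(X, Y, cfg, rng_seed=42)


def make_instance(seed, n=800, lo=-2.0, hi=2.0, config=None):
    """Random regression instance with wide feature spread.

    The wide spread keeps every hidden unit's hinge inside the data region,
    so the combined design matrix is full column rank almost surely (units
    that are affine over the region would be collinear with the direct linear
    block plus a constant).
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, (n, 5))
    Y = rng.normal(0.0, 1.0, (n, 1))
    return X, Y
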