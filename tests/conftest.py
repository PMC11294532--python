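import numpy as np
import pytest

from ftcmap import simscene as sim


@pytest.fixture
def tree_spec():
    return sim.default_tree_spec()


@pytest.fixture
def herb_spec():
    return sim.default_herb_spec()


@pytest.fixture
def zero_cfg():
    """Noise-free, cloud-free, error-free simulation conditions."""
    return sim.SimConfig.zero_error()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def double_logistic(vmin=0.2, vmax=0.8, green_up=12.0, senescence=34.0, steep=2.0):
    """Analytic double-logistic NDVI curve used as a smoothing oracle."""
    c = np.arange(46, dtype=float)
    return vmin + (vmax - vmin) * (
        1.0 / (1.0 + np.exp(-steep * (c - green_up)))
        - 1.0 / (1.0 + np.exp(-steep * (c - senescence)))
    )


@pytest.fixture
def dlog_curve():
    return double_logistic()
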