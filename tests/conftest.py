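import numpy as np
import pytest

from quorumclock.model import ModelParameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    """Default calibrated parameter set."""
    return ModelParameters()


@pytest.fixture
def fast_params():
    """Small, cheap parameter set for integration smoke tests: noise off."""
    return ModelParameters(noise_sigma=0.0, heterogeneity_cv=0.0)
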