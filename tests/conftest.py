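import numpy as np
import pytest

from strokefate.acquisition import AcquisitionConfig
from strokefate.phantom import LesionSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default mid-size lesion phantom with deterministic heterogeneity."""
    return make_phantom(seed=0)


@pytest.fixture(scope="session")
def noiseless_config():
    return AcquisitionConfig(noise_sd=0.0, dsc_noise_sd=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lesion_spec():
    return LesionSpec(center=(29.0, 20.0, 3.5), radii=(5.0, 6.0, 2.5))
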