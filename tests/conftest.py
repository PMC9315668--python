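import numpy as np
import pytest
from hypothesis import settings

from boutonsim import load_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wt_params():
    return load_parameters(condition="WT", coupling="NC")


@pytest.fixture(scope="session")
def ad_params():
    return load_parameters(condition="AD", coupling="NC")


@pytest.fixture(scope="session")
def ad_hc_params():
    return load_parameters(condition="AD", coupling="HC")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
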