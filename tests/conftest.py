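import numpy as np
import pytest

from perfutex import AcquisitionParams, make_population_aif


@pytest.fixture
def params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture
def times(params) -> np.ndarray:
    return params.times


@pytest.fixture
def pop_aif(params, times):
    return make_population_aif(params, times)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
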