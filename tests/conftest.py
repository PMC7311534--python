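import numpy as np
import pytest

from liverperf import AcquisitionParams, DictionaryMatcher, synthesize_inputs
from liverperf.model import default_times


@pytest.fixture(scope="session")
def times():
    return default_times()


@pytest.fixture(scope="session")
def inputs():
    """Canonical synthetic AIF/PVIF on the default 100-frame, 2.4 s grid."""
    return synthesize_inputs()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def matcher(inputs):
    """Default full-resolution dictionary (AF step 0.01, MTT step 1 s)."""
    return DictionaryMatcher(inputs=inputs).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
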