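import numpy as np
import pytest

from exoevo import ParameterSet


@pytest.fixture(scope="session")
def params():
    """Standard microsite parameter set (defaults at system size k = 10)."""
    return ParameterSet.defaults(k=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
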