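import numpy as np
import pytest

from spnpipe.cohort import make_source_space


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def space50():
    """50 vertices per hemisphere (5 x 10 grid each)."""
    return make_source_space(50)


@pytest.fixture(scope="session")
def space100():
    """100 vertices per hemisphere (10 x 10 grid each)."""
    return make_source_space(100)
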