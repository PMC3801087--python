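import numpy as np
import pytest

from corrgate.networks import build_single_unit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_single_unit():
    """One default single-unit network shared by read-only simulator tests."""
    return build_single_unit(np.random.default_rng(7))
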