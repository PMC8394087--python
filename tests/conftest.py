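import numpy as np
import pytest

from ivusreg.synthetic import generate_phantom_pullback


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_small():
    """Short low-resolution phantom shared by fast tests."""
    return generate_phantom_pullback(12, (64, 64), seed=7)


@pytest.fixture(scope="session")
def phantom_frame():
    """One structured 128x128 vessel frame for registration tests."""
    return generate_phantom_pullback(3, (128, 128), seed=11)[1]
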