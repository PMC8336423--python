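import numpy as np
import pytest

from vacdyn.experiments import get_reference


@pytest.fixture(scope="session")
def ou_ref():
    """Full-spectrum grid reference for the 1D OU process."""
    return get_reference("ou1d")


@pytest.fixture(scope="session")
def dw_ref():
    """Grid reference for the 2D double-well diffusion (200 modes)."""
    return get_reference("doublewell2d")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
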