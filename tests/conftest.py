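import numpy as np
import pytest

from minwaves import models


@pytest.fixture
def canonical():
    """Canonical Model II rate set (omega_D=0.1, omega_dD=5, omega_E=0.1,
    omega_ed=100, D=100, omega_e=1, lam=1)."""
    return models.canonical_parameters()


@pytest.fixture
def sphere5():
    return models.Geometry("sphere", 5.0)


@pytest.fixture
def slab256():
    return models.Geometry("slab", 256.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
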