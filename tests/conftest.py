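import numpy as np
import pytest

from hetfpt import DisorderParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def fig5_params():
    """Half-line benchmark parameters: dbar=1, sigma=1, x0=1, tau=2 (nu=1/2)."""
    return DisorderParams(dbar=1.0, sigma=1.0, tau=2.0)


@pytest.fixture
def weak_params():
    """Weak disorder: nu = 2 at tau = 1."""
    return DisorderParams(dbar=1.0, sigma=np.sqrt(0.5), tau=1.0)


@pytest.fixture
def hom_params():
    """Exactly homogeneous diffusion (sigma = 0 sentinel)."""
    return DisorderParams(dbar=1.0, sigma=0.0, tau=1.0)


@pytest.fixture
def near_hom_params():
    """Numerically homogeneous: sigma = 1e-8."""
    return DisorderParams(dbar=1.0, sigma=1e-8, tau=1.0)
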