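import numpy as np
import pytest

from ibcms import FluidParams, FluidState, GridSpec


@pytest.fixture
def grid64():
    return GridSpec.cube(2, 64, 2 * np.pi)


@pytest.fixture
def grid_cm():
    """16 cm box at 64^2, the chamber-scale reference grid."""
    return GridSpec.cube(2, 64, 16.0)


@pytest.fixture
def params():
    return FluidParams(rho=1.0, nu=0.03125, dt=1e-2)


@pytest.fixture
def taylor_green(grid64):
    """k = 1 Taylor-Green vortex on [0, 2pi)^2."""
    X, Y = grid64.meshgrid()
    u = np.stack([np.sin(X) * np.cos(Y), -np.cos(X) * np.sin(Y)])
    return FluidState(u, np.zeros(grid64.n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
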