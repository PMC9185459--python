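"""Shared fixtures: small grids, media and simulated datasets."""

import numpy as np
import pytest

from mwtomo.forward import AntennaArray, simulate_dataset
from mwtomo.grids import build_grid
from mwtomo.medium import BackgroundMedium
from mwtomo.phantoms import PhantomMap


@pytest.fixture(scope="session")
def medium4():
    """Four-frequency background, eps_rb = 10."""
    return BackgroundMedium(10.0, frequencies=np.linspace(2e8, 6e8, 4))


@pytest.fixture(scope="session")
def grid16():
    return build_grid(0.18, 16)


@pytest.fixture(scope="session")
def grid8():
    return build_grid(0.18, 8)


@pytest.fixture(scope="session")
def array8x12():
    return AntennaArray(8, 12, 0.10)


@pytest.fixture(scope="session")
def weak_phantom(grid16):
    """Scatterer with contrast <= 0.01: safely in the Born regime."""
    rng = np.random.default_rng(3)
    eps = np.full(grid16.n_pixels, 10.0)
    mask = np.hypot(grid16.x, grid16.y) < 0.05
    eps[mask] = 10.0 * (1 + 0.01 * rng.random(mask.sum()))
    return PhantomMap(grid16, eps, np.zeros(grid16.n_pixels))


@pytest.fixture(scope="session")
def weak_dataset(weak_phantom, array8x12, medium4):
    """Noiseless same-grid data from the weak scatterer."""
    return simulate_dataset(weak_phantom, array8x12, medium4)
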