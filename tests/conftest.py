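import numpy as np
import pytest

from densityct.phantoms import PhantomImage
from densityct.physics import Spectrum, material_library


@pytest.fixture(scope="session")
def library():
    return material_library()


@pytest.fixture(scope="session")
def water_disk(library):
    """96 mm water disk (radius 35 mm) in air on a 1 mm grid."""
    size = 96
    x = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(x, x)
    grid = np.zeros((size, size), dtype=int)
    grid[xx**2 + yy**2 <= 35.0**2] = 1
    return PhantomImage(grid, 1.0, {0: library["air"], 1: library["water"]})


@pytest.fixture(scope="session")
def mono60():
    """Single-line 60 keV spectrum (padded grid to satisfy the bin minimum)."""
    e = np.arange(51.0, 61.0)
    w = np.zeros(10)
    w[-1] = 1.0
    return Spectrum(60.0, e, w)
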