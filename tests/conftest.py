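import numpy as np
import pytest

from ftirstress.spectra import Spectrum
from ftirstress.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def default_grid():
    """The working grid: 4000 -> 400 cm-1 at 2 cm-1 spacing (1801 points)."""
    return SyntheticConfig().grid()


@pytest.fixture
def random_spectrum(rng, default_grid):
    """A smooth random spectrum (sum of random Gaussian bands) on the grid."""
    y = np.zeros_like(default_grid)
    for _ in range(8):
        c = rng.uniform(600, 3800)
        s = rng.uniform(10, 120)
        a = rng.uniform(0.05, 1.0)
        y += a * np.exp(-0.5 * ((default_grid - c) / s) ** 2)
    return Spectrum(wavenumbers=default_grid, intensities=y)


def make_spectrum(x, y, **meta):
    return Spectrum(wavenumbers=np.asarray(x, float), intensities=np.asarray(y, float), **meta)
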