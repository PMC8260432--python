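import numpy as np
import pytest
from scipy import ndimage

from echosos import Grid, RFFrame, TxDescriptor


def make_speckle_rf(shape=(10, 400), carrier=0.25, pulse_sigma=3.0, seed=0):
    """Synthetic beamformed-RF-like speckle: white scatterers convolved with
    a carrier-modulated Gaussian pulse along the axial axis."""
    rng = np.random.default_rng(seed)
    k = np.arange(-12, 13)
    pulse = np.exp(-k**2 / (2 * pulse_sigma**2)) * np.cos(2 * np.pi * carrier * k)
    return ndimage.convolve1d(rng.standard_normal(shape), pulse, axis=1)


def spectral_shift(values, shift):
    """Exact band-limited axial shift (positive = deeper)."""
    n = values.shape[1]
    f = np.fft.rfftfreq(n)
    return np.fft.irfft(np.fft.rfft(values, axis=1) *
                        np.exp(-2j * np.pi * f * shift), n, axis=1)


def as_frame(values, grid=None, element=0):
    values = np.asarray(values, dtype=float)
    if grid is None:
        nx, nz = values.shape
        grid = Grid(nx, nz, 0.3e-3, 37.5e-6, 0.0, 37.5e-6 / 2)
    return RFFrame(values, np.ones(values.shape, bool), grid,
                   TxDescriptor("dw", element=element), 0.0, "full", 1500.0)


@pytest.fixture
def speckle_pair():
    base = make_speckle_rf()

    def factory(shift):
        return as_frame(spectral_shift(base, shift)), as_frame(base)

    return factory


@pytest.fixture(scope="session")
def small_grid():
    return Grid(16, 16, 1e-3, 1e-3, 0.5e-3, 0.5e-3)
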