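import numpy as np
import pytest

from canosif.synthetic import SpectralTruth, default_grid, simulate_canopy_spectrum


@pytest.fixture
def o2a_grid():
    """Instrument-faithful grid over the O2-A region (0.07 nm sampling)."""
    return default_grid(755.0, 775.0, 0.07)


@pytest.fixture
def noiseless_pair(o2a_grid):
    """Model-consistent noiseless spectrum: quadratic rho, linear F."""
    truth = SpectralTruth(sif_amplitude=1.5, sif_shape="linear", snr=None)
    return simulate_canopy_spectrum(truth, seed=0, grid=o2a_grid), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
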