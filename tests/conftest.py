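import numpy as np
import pytest

import panfat as pf


@pytest.fixture(scope="session")
def slice_pair_96():
    """One medium synthetic water/fat pair, shared across tests."""
    return pf.generate_slice_pair(shape=(96, 96), fat_fraction=8.0, seed=42)


@pytest.fixture(scope="session")
def spmap_96(slice_pair_96):
    """Its LSC superpixel map at the default ratio."""
    return pf.lsc_segment(slice_pair_96.water,
                          pf.LSCParams(n_superpixels=84, r=0.25))


@pytest.fixture(scope="session")
def calibration_curve():
    """Curve fitted on a nearly noiseless phantom series."""
    return pf.fit_calibration(pf.generate_phantom_series(noise_sd=0.1, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
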