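import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dwiqa.protocol import AcquisitionProtocol


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_protocol():
    """2 mm isotropic two-b protocol with a round 100 Hz/px bandwidth."""
    return AcquisitionProtocol(
        b_values=(0.0, 800.0),
        pe_axis=1,
        pe_sign=1,
        bw_pe_px=100.0,
        voxel_size=(2.0, 2.0, 2.0),
        resonance_hz=14.707e6,
    )


@pytest.fixture(scope="session")
def box_object():
    """A smooth-edged bright box in a (24, 40, 24) volume, for warp tests."""
    obj = np.zeros((24, 40, 24))
    obj[6:18, 8:32, 6:18] = 100.0
    return gaussian_filter(obj, 1.5)
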