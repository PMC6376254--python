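import numpy as np
import pytest

from kospec.densitometry import LaneProfile, calibrate_ladder


def gaussian(n, amp, mu, sigma):
    """Noiseless Gaussian band profile on n rows."""
    rows = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((rows - mu) / sigma) ** 2)


@pytest.fixture
def two_anchor_calibration():
    """Exactly log-linear ladder: 50 kDa at row 100, 25 kDa at row 200."""
    return calibrate_ladder([(100, 50.0), (200, 25.0)])


@pytest.fixture
def gaussian_lane():
    """Single noiseless Gaussian band (amp 100, mu 150, sigma 4) on 300 rows."""
    return LaneProfile(values=gaussian(300, 100.0, 150.0, 4.0), lane_id="g")
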