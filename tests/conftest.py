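import numpy as np
import pytest

from denovoscan import calibration as calib


@pytest.fixture(scope="session")
def calib_table():
    """Small but well-resolved calibration shared across tests."""
    rng = np.random.default_rng(7)
    return calib.build_calibration(
        (15, 25, 50, 100, 200, 500), n_reps=200, rng=rng
    )


@pytest.fixture(scope="session")
def tiny_calib_table():
    """Coarse calibration for plumbing tests that only need a valid table."""
    rng = np.random.default_rng(3)
    return calib.build_calibration(
        (15, 25, 50, 100, 200), n_reps=60, rng=rng
    )
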