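import numpy as np
import pytest

from filmqa import build_calibration
from filmqa import synthetic as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def noiseless_calibration():
    """Calibration built from noise-free synthetic exposures: the fitted
    rational curve then matches the generator's response exactly."""
    rng = np.random.default_rng(0)
    points, pv0 = syn.generate_calibration(rng, noise_sigma=0.0)
    return build_calibration(points, "rational", unexposed_pixel_value=pv0)


@pytest.fixture(scope="session")
def noisy_calibration():
    rng = np.random.default_rng(11)
    points, pv0 = syn.generate_calibration(rng)
    return build_calibration(points, "rational", unexposed_pixel_value=pv0)


@pytest.fixture(scope="session")
def imrt_plan():
    return syn.example_imrt_plans()[0]
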