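import numpy as np
import pytest

from valvect import phantom as ph
from valvect.pipeline import quantify_volume


@pytest.fixture(scope="session")
def clean_phantom():
    """Default valve phantom, no noise or blur."""
    return ph.generate_valve_phantom(ph.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_result(clean_phantom):
    return quantify_volume(clean_phantom.volume, clean_phantom.plane)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default geometry under sigma=15 HU noise and 1-pixel blur."""
    spec = ph.PhantomSpec(seed=1, blood_pool_noise_sd=15.0, blur_sigma_px=1.0)
    return ph.generate_valve_phantom(spec)


@pytest.fixture(scope="session")
def noisy_result(noisy_phantom):
    return quantify_volume(noisy_phantom.volume, noisy_phantom.plane)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
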