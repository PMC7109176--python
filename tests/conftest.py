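import numpy as np
import pytest

from petgmm import PhantomSpec, make_phantom
from petgmm.image import ScalarSlice, crop


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """A high-contrast untreated lesion phantom with a clean reference."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def treated_phantom():
    """A heavily treated lesion whose maximum SUV drops below 2.5."""
    return make_phantom(PhantomSpec(treatment_effect=0.9, seed=9))


@pytest.fixture()
def cropped_suv(default_phantom):
    return crop(default_phantom.suv, default_phantom.crop)
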