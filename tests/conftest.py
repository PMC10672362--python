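import numpy as np
import pytest

from octshot import speckle_sim as ss
from octshot import system_model as sm


@pytest.fixture(scope="session")
def chicken_spec():
    return sm.load_system("chicken")


@pytest.fixture(scope="session")
def chicken_psf(chicken_spec):
    return sm.system_psf(chicken_spec)


@pytest.fixture(scope="session")
def small_pair(chicken_spec):
    """A compact speckled/clean tomogram pair for training sanity checks."""
    return ss.make_pair(chicken_spec, 64, 96, seed=0)


@pytest.fixture()
def ramp_image():
    values = np.arange(20 * 20, dtype=float).reshape(20, 20)
    return ss.LogImage(values=values)
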