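import numpy as np
import pytest

from glcsa.data_io import ImageVolume, ZoneMask
from glcsa.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom_pair():
    spec = PhantomSpec(shape=(8, 32, 32), noise_sigma=5.0, seed=42)
    return generate_phantom(spec)


@pytest.fixture
def pp_pair():
    """A 320x320 raw pair, as acquired, for preprocessing tests."""
    rng = np.random.default_rng(9)
    img = rng.random((12, 320, 320)) * 900.0 + 50.0
    lab = np.zeros((12, 320, 320), dtype=np.int16)
    lab[3:9, 140:180, 150:190] = 1
    lab[3:9, 180:210, 150:190] = 2
    return ImageVolume(img), ZoneMask(lab)


def assert_allclose(a, b, tol=1e-6, msg=""):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    err = np.abs(a - b).max() if a.size else 0.0
    assert err <= tol, f"{msg} max abs err {err} > {tol}"
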