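import numpy as np
import pytest

from erbs.descriptor import DescriptorSettings
from erbs.system import AtomicConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_settings():
    return DescriptorSettings(cutoff=4.0, n_radial=3)


@pytest.fixture
def random_cluster(rng):
    """Five carbon atoms in a ~2 Å blob, all within cutoff of each other."""
    pos = rng.normal(scale=1.2, size=(5, 3))
    return AtomicConfiguration(pos, [6] * 5)


def random_rotation(rng):
    """Haar-random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
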