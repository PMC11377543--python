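import numpy as np
import pytest

from polypvit.model import ArchConfig
from polypvit.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchConfig.tiny()


@pytest.fixture(scope="session")
def tiny_synth_config():
    return SyntheticConfig(image_size=64, radius_range=(0.1, 0.25), seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_config):
    return generate_dataset(12, tiny_synth_config, seed=99)


def numeric_gradient(fn, x, eps=1e-6):
    """Central-difference gradient of scalar fn at array x."""
    x = np.asarray(x, dtype=np.float64)
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return grad
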