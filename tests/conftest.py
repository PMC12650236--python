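import numpy as np
import pytest

from cacseg.imaging_io import CTVolume
from cacseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic 64-cube phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A smaller, cheaper phantom for cascade/fusion plumbing tests."""
    return generate_phantom(PhantomSpec(
        shape=(40, 48, 48), heart_semiaxes_mm=(14.0, 16.0, 16.0),
        n_branches=2, n_calcifications=3, n_decoys=2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(voxels, spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    return CTVolume(np.asarray(voxels, dtype=np.float32), spacing=spacing)
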