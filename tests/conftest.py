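import numpy as np
import pytest

from wavepool.phantom import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """A small 64x64 phantom set shared by slower integration tests."""
    spec = PhantomSpec(size=64, lesion_contrast=0.35, texture_amplitude=0.05)
    samples, manifest = generate_dataset(60, 0.5, spec, seed=777)
    return samples, manifest
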