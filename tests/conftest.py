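import numpy as np
import pytest

from sdsseg.network import NetworkConfig
from sdsseg.phantom import PhantomSpec, generate_phantom
from sdsseg.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def desk_precfg():
    return PreprocessConfig(crop_size=(56, 56), input_size=(64, 64))


@pytest.fixture(scope="session")
def small_phantom():
    """A 16x64x64 four-modality phantom with mild noise."""
    return generate_phantom(PhantomSpec(shape=(16, 64, 64), seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise phantom: intensities exactly equal region means."""
    return generate_phantom(PhantomSpec(shape=(16, 64, 64), noise_sigma=0.0, seed=5))


@pytest.fixture(scope="session")
def tiny_netcfg():
    """Smallest usable network: 16x16 inputs, 3 context slices, 1 modality."""
    return NetworkConfig(base_channels=4, in_plane=(16, 16), context_slices=3,
                         n_modalities=1, seed=0)


def random_masks(rng, shape=(8, 8, 4), p=0.3):
    return rng.random(shape) < p
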