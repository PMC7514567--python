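import numpy as np
import pytest

from cvmstage import synthdata


@pytest.fixture(scope="session")
def clean_generator():
    """Zero-noise, zero-jitter generator: geometry is exactly stage-true."""
    return synthdata.GeneratorConfig(
        image_size=64, n_per_class=5, noise_sd=0.0, rotation_jitter=0.0,
        scale_jitter=0.0, gradient_amplitude=0.0, seed=7)


@pytest.fixture(scope="session")
def tiny_train_data():
    """Small easy 32-px dataset shared by the training tests."""
    gen = synthdata.easy_preset(image_size=32, n_per_class=18, seed=11)
    samples = synthdata.generate_samples(gen)
    return {
        split: synthdata.samples_to_arrays(samples, split)
        for split in synthdata.SPLIT_NAMES
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
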