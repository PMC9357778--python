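import numpy as np
import pytest

from neuroseg import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_phantom():
    return synthetic.generate_phantom(
        size=64, tumor=False, noise_kind="salt_pepper",
        noise_level=0.05, seed=0)


@pytest.fixture
def clean_phantom():
    return synthetic.generate_phantom(size=64, tumor=True, seed=1)
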