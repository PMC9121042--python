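import numpy as np
import pytest

from vstseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 64x64 phantom slice with all six structures."""
    return generate_phantom(PhantomSpec(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise 64x64 phantom slice."""
    return generate_phantom(PhantomSpec(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
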