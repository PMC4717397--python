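import numpy as np
import pytest

from synovol.imaging import IntensityModel
from synovol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom with its ground truth."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with noise at 10% of the tissue-fluid contrast."""
    return generate_phantom(PhantomSpec(post_noise_sd=20.0, pre_noise_sd=10.0, seed=0))


@pytest.fixture
def default_model():
    return IntensityModel(m_f=100.0, m_s=300.0)
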