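import numpy as np
import pytest

from phagoquant.imaging import Image2D
from phagoquant.synthetic import SyntheticSectionSpec, generate_section


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_section():
    """A noise-free synthetic section (shared; treat as read-only)."""
    return generate_section(SyntheticSectionSpec(noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def noisy_section():
    """A synthetic section at the default noise level (shared; read-only)."""
    return generate_section(SyntheticSectionSpec(noise_sd=5.0, seed=42))


@pytest.fixture
def random_image(rng):
    return Image2D(rng.uniform(0, 100, (32, 32)))
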