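import numpy as np
import pytest

from ctdenoise import Image, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_img() -> Image:
    """Default 256x256 textured phantom (session-wide, read-only)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_phantom() -> Image:
    """128x128 phantom for tests where full-size runs would be slow."""
    return generate_phantom(PhantomSpec(shape=(128, 128), seed=1))


@pytest.fixture(scope="session")
def flat_phantom() -> Image:
    """Texture-free (exactly 3-valued) phantom."""
    return generate_phantom(PhantomSpec(texture_amp=0.0, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
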