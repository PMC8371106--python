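import numpy as np
import pytest

from pomgrade.grades import PREMIUM
from pomgrade.sample import ImageSample
from pomgrade.synthgen import SynthConfig, generate_apple_image


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Fast 64x64 generator configuration shared across tests."""
    return SynthConfig(image_size=(64, 64), seed=42)


@pytest.fixture(scope="session")
def apple_image(small_cfg) -> ImageSample:
    return generate_apple_image(PREMIUM, small_cfg, fruit_seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_image(pixels, label=PREMIUM, fruit_id=0, **kw) -> ImageSample:
    return ImageSample(pixels=np.asarray(pixels, dtype=np.uint8),
                       label=label, fruit_id=fruit_id, **kw)
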