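import numpy as np
import pytest

from atsvit.model import ViTATS, ViTConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A 64x64 grayscale model small enough for per-test training."""
    return ViTConfig(image_size=64, channels=1, patch_size=16, dim=32,
                     depth=2, heads=2, num_classes=2, token_schedule=(16, 8),
                     seed=0)


@pytest.fixture
def tiny_model(tiny_config):
    return ViTATS(tiny_config)


@pytest.fixture
def tiny_images(rng):
    return [rng.random((64, 64)) for _ in range(8)]
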