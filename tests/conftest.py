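import numpy as np
import pytest

from mrpunet.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model_config():
    """A 32-pixel, narrow-width config for fast structural tests."""
    return ModelConfig(input_size=32, level_channels=[4, 8, 16, 32],
                       bottleneck_channels=64, se_reduction=4)
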