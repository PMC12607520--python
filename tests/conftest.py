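import numpy as np
import pytest

from endomoe.model import ModelConfig, build_model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TINY_MODEL = dict(
    num_classes=2,
    experts_per_stage=2,
    base_channels=8,
    bottleneck_channels=8,
    conv_groups=4,
    se_reduction=8,
    attn_reduction=8,
)


@pytest.fixture()
def tiny_model():
    """A very small but architecturally complete model (2 experts/stage)."""
    return build_model(ModelConfig(seed=7, **TINY_MODEL))

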