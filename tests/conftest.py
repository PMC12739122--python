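import numpy as np
import pytest

from beatfusion.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest geometry that still exercises every architectural path."""
    return ModelConfig(
        window_len=64,
        class_num=3,
        channels=(4, 8),
        seq_len=6,
        d_feature=8,
        d_model=12,
        n_layers=2,
        n_head=2,
        d_k=6,
        d_v=6,
        d_inner=16,
        d_fusion=8,
        fusion_heads=2,
        dropout=0.0,
        dropout1=0.0,
    )
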