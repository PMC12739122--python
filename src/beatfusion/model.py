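"""End-to-end beat classifier: CNN encoder → transformer encoder → fusion.

The CNN stream C (local morphology) and the transformer stream B (global
context over the CNN features) are emitted at the same sequence length T by
construction, cross-attended and gate-fused, and classified from the pooled
fused sequence concatenated with the [CLS] summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Module, load_checkpoint, save_checkpoint
from ._tensor import Tensor
from .bert import BertEncoder, EncoderConfig
from .cnn import CNNEncoder, ConvSpec
from .fusion import FusionClassifier, FusionConfig

__all__ = ["ModelConfig", "BeatClassifierModel"]


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter of the classifier."""

    window_len: int = 360
    class_num: int = 5
    channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    pool_window: int = 2
    dropout1: float = 0.3  # CNN dropout
    seq_len: int = 16  # T: time steps emitted by both encoder streams
    d_feature: int = 64  # d_c: CNN feature dim per time step
    d_model: int = 256
    n_layers: int = 4
    n_head: int = 4
    d_k: int = 64
    d_v: int = 64
    d_inner: int = 512
    dropout: float = 0.1  # transformer dropout
    d_fusion: int = 64  # shared fusion dim d
    fusion_heads: int = 1

    def conv_specs(self) -> list[ConvSpec]:
        chain = (1,) + tuple(self.channels)
        return [
            ConvSpec(a, b, self.kernel_size, self.pool_window, self.dropout1)
            for a, b in zip(chain, chain[1:])
        ]

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            n_layers=self.n_layers,
            n_heads=self.n_head,
            d_model=self.d_model,
            d_k=self.d_k,
            d_v=self.d_v,
            d_inner=self.d_inner,
            dropout_rate=self.dropout,
            max_len=self.seq_len + 1,  # + [CLS]
        )

    def fusion_config(self) -> FusionConfig:
        return FusionConfig(d_c=self.d_feature, d_b=self.d_model, d=self.d_fusion, h=self.fusion_heads)

    @staticmethod
    def reduced(class_num: int = 5, window_len: int = 360) -> "ModelConfig":
        """Desk-scale geometry used by the test-time training runs."""
        return ModelConfig(
            window_len=window_len,
            class_num=class_num,
            channels=(8, 16),
            seq_len=16,
            d_feature=32,
            d_model=32,
            n_layers=2,
            n_head=2,
            d_k=16,
            d_v=16,
            d_inner=64,
            d_fusion=32,
        )


class BeatClassifierModel(Module):
    """CNN + transformer encoders with cross-modal gated fusion head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.config = config
        self.cnn = CNNEncoder(
            config.window_len, config.conv_specs(), config.seq_len, config.d_feature, rng
        )
        self.encoder = BertEncoder(config.d_feature, config.encoder_config(), rng, d_out=config.d_model)
        self.fusion = FusionClassifier(
            config.fusion_config(), d_summary=config.d_model, n_classes=config.class_num, rng=rng
        )

    def forward(
        self,
        beats: np.ndarray | Tensor,
        rng: np.random.Generator | None = None,
        train_mode: bool = False,
        freeze_encoders: bool = False,
    ) -> Tensor:
        """Batch of beats (n, window_len) → class probabilities (n, class_num)."""
        rng = rng if rng is not None else np.random.default_rng(0)
        C = self.cnn.forward(beats, rng, train_mode)
        B, summary = self.encoder.forward(C, rng, train_mode)
        if freeze_encoders:
            C, B, summary = C.detach(), B.detach(), summary.detach()
        return self.fusion.forward(C, B, summary)

    def predict(self, beats: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic class predictions (integer indices into the vocabulary)."""
        rng = np.random.default_rng(0)  # unused: dropout is off in eval mode
        out = []
        for lo in range(0, len(beats), batch_size):
            probs = self.forward(beats[lo : lo + batch_size], rng, train_mode=False)
            out.append(probs.data.argmax(axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)

    def save(self, path, meta: dict | None = None) -> None:
        save_checkpoint(path, self.parameters(), meta)

    def load(self, path) -> dict:
        return load_checkpoint(path, self.parameters())
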