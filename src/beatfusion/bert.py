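"""Global sequence modeling with a BERT-style bidirectional encoder.

The CNN feature sequence is projected into the model space by a 1-D
convolutional embedding (``same`` padding, so the length is preserved), a
learned [CLS] vector is prepended, learned positional embeddings are added,
and the sequence runs through a stack of pre-LayerNorm transformer encoder
layers (multi-head scaled dot-product attention + position-wise FFN, both
residual).  Padding positions are masked out of the attention.  A trailing
lightweight convolution compresses the encoded sequence for the fusion
stage; the [CLS] output is the whole-sequence summary.

Defaults follow the 256-dim / 4-head / 4-layer geometry with 64-dim heads;
the larger 768-dim / 12-head geometry is reachable through the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._nn import LayerNorm, Linear, Module, kaiming_uniform
from ._tensor import Tensor

__all__ = ["EncoderConfig", "scaled_dot_attention", "MultiHeadAttention", "EncoderLayer", "BertEncoder"]

_MASK_FILL = -1e30  # logit for masked keys; underflows to exactly 0 after softmax


class DegenerateMaskError(ValueError):
    """Raised when every key is masked for some query."""


@dataclass(frozen=True)
class EncoderConfig:
    """Geometry of the transformer encoder stack."""

    n_layers: int = 4
    n_heads: int = 4
    d_model: int = 256
    d_k: int = 64
    d_v: int = 64
    d_inner: int = 512
    dropout_rate: float = 0.1
    max_len: int = 64

    def __post_init__(self) -> None:
        if min(self.n_layers, self.n_heads, self.d_model, self.d_k, self.d_v, self.d_inner, self.max_len) < 1:
            raise ValueError("all encoder dimensions must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """softmax(QKᵀ/√d_k)V with masked keys excluded (reference numpy form).

    Q: (n_q, d_k); K: (n_k, d_k); V: (n_k, d_v); mask: boolean key validity.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must share the key count")
    logits = Q @ K.T / np.sqrt(Q.shape[-1])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DegenerateMaskError("every key is masked")
        logits = np.where(mask[None, :], logits, _MASK_FILL)
    logits = logits - logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


def _masked_softmax(logits: Tensor, key_mask: np.ndarray | None) -> Tensor:
    """Softmax over the last axis with invalid keys forced to ~0 weight."""
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=bool)
        if not key_mask.any(axis=-1).all():
            raise DegenerateMaskError("a query has every key masked")
        fill = np.where(key_mask, 0.0, _MASK_FILL)
        # broadcast (batch, keys) over (batch, heads, queries, keys)
        logits = logits + fill[:, None, None, :]
    return T.softmax(logits, axis=-1)


class MultiHeadAttention(Module):
    """Project to per-head Q/K/V, attend, concatenate heads, project back."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.w_q = Linear(c.d_model, c.n_heads * c.d_k, rng)
        self.w_k = Linear(c.d_model, c.n_heads * c.d_k, rng)
        self.w_v = Linear(c.d_model, c.n_heads * c.d_v, rng)
        self.w_o = Linear(c.n_heads * c.d_v, c.d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        c = self.config
        B, L, _ = x.shape

        def split_heads(t: Tensor, d: int) -> Tensor:
            return t.reshape(B, L, c.n_heads, d).transpose((0, 2, 1, 3))

        q = split_heads(self.w_q(x), c.d_k)
        k = split_heads(self.w_k(x), c.d_k)
        v = split_heads(self.w_v(x), c.d_v)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(c.d_k))
        weights = _masked_softmax(logits, key_mask)
        heads = weights @ v  # (B, h, L, d_v)
        merged = heads.transpose((0, 2, 1, 3)).reshape(B, L, c.n_heads * c.d_v)
        return self.w_o(merged)


class EncoderLayer(Module):
    """Pre-LayerNorm transformer layer: x + MHA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.ln1 = LayerNorm(config.d_model)
        self.mha = MultiHeadAttention(config, rng)
        self.ln2 = LayerNorm(config.d_model)
        self.ff1 = Linear(config.d_model, config.d_inner, rng)
        self.ff2 = Linear(config.d_inner, config.d_model, rng)

    def __call__(
        self,
        x: Tensor,
        key_mask: np.ndarray | None,
        rng: np.random.Generator,
        train_mode: bool,
    ) -> Tensor:
        p = self.config.dropout_rate
        h = x + T.dropout(self.mha(self.ln1(x), key_mask), p, rng, train_mode)
        ff = self.ff2(self.ff1(self.ln2(h)).relu())
        return h + T.dropout(ff, p, rng, train_mode)


class BertEncoder(Module):
    """Conv embedding → [CLS] + positions → encoder stack → trailing conv."""

    def __init__(self, d_in: int, config: EncoderConfig, rng: np.random.Generator, d_out: int | None = None):
        c = config
        self.config = c
        self.d_out = d_out if d_out is not None else c.d_model
        # convolutional embedding ('same' padding preserves sequence length)
        self.embed_weight = Tensor(
            kaiming_uniform(rng, (c.d_model, d_in, 3), fan_in=3 * d_in), requires_grad=True
        )
        self.embed_bias = Tensor(np.zeros(c.d_model), requires_grad=True)
        self.cls = Tensor(rng.normal(0.0, 0.02, size=(1, 1, c.d_model)), requires_grad=True)
        self.positions = Tensor(rng.normal(0.0, 0.02, size=(c.max_len, c.d_model)), requires_grad=True)
        self.layers = [EncoderLayer(c, rng) for _ in range(c.n_layers)]
        self.ln_final = LayerNorm(c.d_model)
        # trailing lightweight conv compressing the sequence representation
        self.tail_weight = Tensor(
            kaiming_uniform(rng, (self.d_out, c.d_model, 3), fan_in=3 * c.d_model), requires_grad=True
        )
        self.tail_bias = Tensor(np.zeros(self.d_out), requires_grad=True)

    def positional_table(self) -> Tensor:
        """The learned (max_len, d_model) positional-embedding table."""
        return self.positions

    def forward(
        self,
        features: Tensor | np.ndarray,
        rng: np.random.Generator,
        train_mode: bool = False,
        mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Encode a (batch, T, d_in) feature sequence.

        Returns (encoded sequence (batch, T, d_out), [CLS] summary
        (batch, d_model)).  `mask` flags valid time steps; padding steps are
        excluded from attention and cannot influence the summary.
        """
        x = features if isinstance(features, Tensor) else Tensor(features)
        B, L, _ = x.shape
        c = self.config
        if L + 1 > c.max_len:
            raise ValueError(f"sequence length {L}+[CLS] exceeds max_len={c.max_len}")
        if mask is None:
            mask = np.ones((B, L), dtype=bool)
        # embed: conv over time requires (B, channels, L)
        h = T.conv1d(x.swapaxes(1, 2), self.embed_weight, self.embed_bias, padding="same")
        h = h.swapaxes(1, 2)  # (B, L, d_model)
        cls = self.cls * Tensor(np.ones((B, 1, 1)))
        h = T.concat([cls, h], axis=1)
        h = h + self.positions[: L + 1]
        full_mask = np.concatenate([np.ones((B, 1), dtype=bool), mask], axis=1)
        h = T.dropout(h, c.dropout_rate, rng, train_mode)
        for layer in self.layers:
            h = layer(h, full_mask, rng, train_mode)
        h = self.ln_final(h)
        summary = h[:, 0, :]
        body = h[:, 1:, :]
        # zero padded steps so the trailing conv cannot leak them inward
        body = body * Tensor(mask[:, :, None].astype(np.float64))
        encoded = T.conv1d(body.swapaxes(1, 2), self.tail_weight, self.tail_bias, padding="same")
        return encoded.swapaxes(1, 2), summary
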