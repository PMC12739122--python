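"""Local morphological feature extraction with stacked 1-D convolutions.

Each block applies conv (valid padding) → ReLU → non-overlapping max pool
→ dropout, with a residual shortcut that inserts a 1×1 convolution only
when the channel counts differ; the shortcut is center-cropped to the conv
output length and pooled with the same window so shapes align.  A final
fully connected map reshapes the features to a fixed (out_len × out_dim)
sequence for the transformer stage.

The module also exposes reference numpy implementations of the three
primitive ops (``conv1d``, ``relu``, ``maxpool``); the trainable encoder is
checked against them in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._nn import Linear, Module, kaiming_uniform
from ._tensor import Tensor

__all__ = ["ConvSpec", "conv1d", "relu", "maxpool", "CNNEncoder"]


@dataclass(frozen=True)
class ConvSpec:
    """One convolutional block: conv → ReLU → max pool → dropout."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    pool_window: int = 2
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.pool_window < 1:
            raise ValueError("pool_window must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")


def conv1d(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid 1-D convolution: y_t = Σ_k ω_k · x_{t−k+1} + bias.

    The kernel slides over every position where its full support is in
    range, so the output has length len(x) − K + 1.  Note the indexing
    runs backward over the kernel (true convolution, not correlation).
    """
    x = np.asarray(x, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.size == 0:
        raise ValueError("kernel must be non-empty")
    if x.size < kernel.size:
        raise ValueError("input shorter than kernel")
    return np.convolve(x, kernel, mode="valid") + bias


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def maxpool(x: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping max pooling; a trailing partial window is pooled as-is."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot pool an empty input")
    if window < 1:
        raise ValueError("pool window must be >= 1")
    n_out = -(-x.size // window)
    return np.array([x[i * window : (i + 1) * window].max() for i in range(n_out)])


class _ConvBlock(Module):
    def __init__(self, spec: ConvSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = spec.in_channels * spec.kernel_size
        self.weight = Tensor(
            kaiming_uniform(rng, (spec.out_channels, spec.in_channels, spec.kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(spec.out_channels), requires_grad=True)
        # residual 1x1 conv only when the channel counts differ
        if spec.in_channels != spec.out_channels:
            self.res_weight = Tensor(
                kaiming_uniform(rng, (spec.out_channels, spec.in_channels, 1), spec.in_channels),
                requires_grad=True,
            )
        else:
            self.res_weight = None

    def __call__(self, x: Tensor, rng: np.random.Generator, train_mode: bool) -> Tensor:
        spec = self.spec
        y = T.conv1d(x, self.weight, self.bias, padding="valid").relu()
        y = T.maxpool1d(y, spec.pool_window)
        # shortcut: channel-match, center-crop to the conv output length, pool
        shortcut = x if self.res_weight is None else T.conv1d(x, self.res_weight)
        crop = (x.shape[-1] - (x.shape[-1] - spec.kernel_size + 1)) // 2
        if crop:
            shortcut = shortcut[:, :, crop : crop + x.shape[-1] - spec.kernel_size + 1]
        y = y + T.maxpool1d(shortcut, spec.pool_window)
        return T.dropout(y, spec.dropout_rate, rng, train_mode)


class CNNEncoder(Module):
    """Stacked conv blocks plus a fully connected fixed-length projection.

    forward() maps a batch of beats (batch, window_len) to a feature
    sequence (batch, out_len, out_dim) with an all-valid mask: the input
    beats are fixed-length, so no padding arises at this stage.
    """

    def __init__(
        self,
        window_len: int,
        specs: list[ConvSpec],
        out_len: int,
        out_dim: int,
        rng: np.random.Generator,
    ):
        if not specs:
            raise ValueError("at least one conv block required")
        if specs[0].in_channels != 1:
            raise ValueError("first block must take the single-lead input (in_channels=1)")
        for a, b in zip(specs, specs[1:]):
            if a.out_channels != b.in_channels:
                raise ValueError("channel counts must chain between blocks")
        self.window_len = window_len
        self.out_len = out_len
        self.out_dim = out_dim
        self.blocks = [_ConvBlock(s, rng) for s in specs]
        L = window_len
        for s in specs:
            L = -(-(L - s.kernel_size + 1) // s.pool_window)
            if L < 1:
                raise ValueError("window too short for the configured blocks")
        self._flat_dim = L * specs[-1].out_channels
        self.fc = Linear(self._flat_dim, out_len * out_dim, rng)

    def forward(self, beats: Tensor | np.ndarray, rng: np.random.Generator, train_mode: bool = False) -> Tensor:
        x = beats if isinstance(beats, Tensor) else Tensor(beats)
        if x.ndim != 2 or x.shape[1] != self.window_len:
            raise ValueError(f"expected (batch, {self.window_len}) beats, got {x.shape}")
        h = x.reshape(x.shape[0], 1, x.shape[1])
        for block in self.blocks:
            h = block(h, rng, train_mode)
        flat = h.reshape(h.shape[0], self._flat_dim)
        seq = self.fc(flat).reshape(x.shape[0], self.out_len, self.out_dim)
        return seq
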