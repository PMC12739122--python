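"""Cross-modal alignment and gated fusion of the CNN and encoder streams.

Both feature sequences are projected to a shared dimension d, the CNN
stream queries the encoder stream through multi-head cross attention

    A = softmax((C'W_Q)(B'W_K)ᵀ / √d_k),   F_CB = A (B'W_V),

and a sigmoid gate blends the two elementwise:

    g_t = σ(W_g [C'_t ; F_CB,t] + b_g),   F_t = g_t ⊙ C'_t + (1−g_t) ⊙ F_CB,t,

so every fused element lies between its two sources by construction.  With
h = 1 the attention reduces to the single-matrix form.  The classifier
mean-pools the fused sequence over valid steps, concatenates the [CLS]
summary, and applies a linear softmax layer.

Reference numpy implementations of each step are exposed alongside the
trainable module and serve as its oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._nn import Linear, Module
from ._tensor import Tensor

__all__ = [
    "FusionConfig",
    "FusionParameters",
    "project_features",
    "cross_modal_attention",
    "gated_fusion",
    "classify",
    "FusionClassifier",
]


@dataclass(frozen=True)
class FusionConfig:
    d_c: int  # CNN feature dim
    d_b: int  # encoder feature dim
    d: int  # shared projection dim
    h: int = 1  # attention heads

    def __post_init__(self) -> None:
        if min(self.d_c, self.d_b, self.d, self.h) < 1:
            raise ValueError("all fusion dimensions must be >= 1")
        if self.d % self.h:
            raise ValueError("d must be divisible by h")

    @property
    def d_k(self) -> int:
        return self.d // self.h


@dataclass
class FusionParameters:
    """Plain-array parameters for the reference (numpy) fusion path."""

    W_c: np.ndarray  # (d_c, d)
    b_c: np.ndarray  # (d,)
    W_b: np.ndarray  # (d_b, d)
    b_b: np.ndarray  # (d,)
    W_Q: np.ndarray  # (d, d)
    W_K: np.ndarray  # (d, d)
    W_V: np.ndarray  # (d, d)
    W_g: np.ndarray  # (2d, d)
    b_g: np.ndarray  # (d,)


def project_features(
    C: np.ndarray, B: np.ndarray, params: FusionParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Affine maps into the shared dimension: C' = C W_c + b_c, B' = B W_b + b_b."""
    C, B = np.asarray(C, dtype=np.float64), np.asarray(B, dtype=np.float64)
    if C.shape[0] != B.shape[0]:
        raise ValueError("C and B must share the number of time steps")
    if C.shape[1] != params.W_c.shape[0] or B.shape[1] != params.W_b.shape[0]:
        raise ValueError("feature dims do not match projection parameters")
    return C @ params.W_c + params.b_c, B @ params.W_b + params.b_b


def cross_modal_attention(
    Cp: np.ndarray, Bp: np.ndarray, params: FusionParameters, config: FusionConfig
) -> np.ndarray:
    """Per-head softmax((C'W_Q)(B'W_K)ᵀ/√d_k)(B'W_V), heads concatenated."""
    Cp, Bp = np.asarray(Cp, dtype=np.float64), np.asarray(Bp, dtype=np.float64)
    q, k, v = Cp @ params.W_Q, Bp @ params.W_K, Bp @ params.W_V
    d_k = config.d_k
    out = np.empty((Cp.shape[0], config.d))
    for head in range(config.h):
        sl = slice(head * d_k, (head + 1) * d_k)
        logits = q[:, sl] @ k[:, sl].T / np.sqrt(d_k)
        logits -= logits.max(axis=-1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=-1, keepdims=True)
        out[:, sl] = w @ v[:, sl]
    return out


def gated_fusion(Cp: np.ndarray, F_cb: np.ndarray, params: FusionParameters) -> np.ndarray:
    """Sigmoid-gated convex combination of the two aligned streams."""
    Cp, F_cb = np.asarray(Cp, dtype=np.float64), np.asarray(F_cb, dtype=np.float64)
    z = np.concatenate([Cp, F_cb], axis=-1) @ params.W_g + params.b_g
    g = 1.0 / (1.0 + np.exp(-z))
    return g * Cp + (1.0 - g) * F_cb


def classify(
    F: np.ndarray,
    summary: np.ndarray,
    head_weights: tuple[np.ndarray, np.ndarray],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean-pool F over valid steps, concat the summary, linear + softmax."""
    F, summary = np.asarray(F, dtype=np.float64), np.asarray(summary, dtype=np.float64)
    W, b = head_weights
    if W.shape[1] < 2:
        raise ValueError("need at least two classes")
    if mask is None:
        pooled = F.mean(axis=0)
    else:
        mask = np.asarray(mask, dtype=bool)
        pooled = F[mask].mean(axis=0)
    z = np.concatenate([pooled, summary]) @ W + b
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


class FusionClassifier(Module):
    """Trainable fusion + classification head on the autodiff engine."""

    def __init__(self, config: FusionConfig, d_summary: int, n_classes: int, rng: np.random.Generator):
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.config = config
        self.proj_c = Linear(config.d_c, config.d, rng)
        self.proj_b = Linear(config.d_b, config.d, rng)
        self.w_q = Linear(config.d, config.d, rng, bias=False)
        self.w_k = Linear(config.d, config.d, rng, bias=False)
        self.w_v = Linear(config.d, config.d, rng, bias=False)
        self.gate = Linear(2 * config.d, config.d, rng)
        self.head = Linear(config.d + d_summary, n_classes, rng)

    def fuse(self, C: Tensor, B: Tensor) -> Tensor:
        """(batch, T, d_c) × (batch, T, d_b) → fused (batch, T, d)."""
        c = self.config
        Cp, Bp = self.proj_c(C), self.proj_b(B)
        Bsz, L, _ = Cp.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(Bsz, L, c.h, c.d_k).transpose((0, 2, 1, 3))

        q, k, v = split(self.w_q(Cp)), split(self.w_k(Bp)), split(self.w_v(Bp))
        weights = T.softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(c.d_k)), axis=-1)
        f_cb = (weights @ v).transpose((0, 2, 1, 3)).reshape(Bsz, L, c.d)
        g = self.gate(T.concat([Cp, f_cb], axis=-1)).sigmoid()
        return g * Cp + (1.0 - g) * f_cb

    def forward(self, C: Tensor, B: Tensor, summary: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Class probabilities (batch, n_classes)."""
        fused = self.fuse(C, B)
        if mask is not None:
            m = mask.astype(np.float64)
            pooled = (fused * Tensor(m[:, :, None])).sum(axis=1) * Tensor(
                (1.0 / np.maximum(m.sum(axis=1), 1.0))[:, None]
            )
        else:
            pooled = fused.mean(axis=1)
        z = self.head(T.concat([pooled, summary], axis=-1))
        return T.softmax(z, axis=-1)
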