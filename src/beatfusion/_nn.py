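"""Parameter containers and the few generic layers shared by the encoders.

Modules hold named ``Tensor`` parameters and expose them as a flat
``{"path/name": Tensor}`` mapping so every stage of the model shares one
checkpoint format (a numpy ``.npz`` keyed by parameter path).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "kaiming_uniform", "save_checkpoint", "load_checkpoint"]


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style uniform init, the default for ReLU networks; bound = sqrt(6/fan_in)."""
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal module: child modules and parameters discovered via attributes."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[path] = value
            elif isinstance(value, Module):
                out.update(value.parameters(prefix=f"{path}/"))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{path}.{i}/"))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{path}.{i}"] = item
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


class Linear(Module):
    """Affine map x @ W + b with Kaiming-uniform weights and zero bias."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(kaiming_uniform(rng, (d_in, d_out), fan_in=d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalize the last axis to zero mean / unit variance, then scale and shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        y = centered * (var + self._eps) ** -0.5
        return y * self.gamma + self.beta


def save_checkpoint(path, params: dict[str, Tensor], meta: dict | None = None) -> None:
    """Persist parameters (and optional scalar metadata) as an .npz archive."""
    arrays = {k: p.data for k, p in params.items()}
    if meta:
        for k, v in meta.items():
            arrays[f"__meta__/{k}"] = np.asarray(v)
    np.savez(path, **arrays)


def load_checkpoint(path, params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    """Load parameter values in place; returns any metadata stored alongside."""
    with np.load(path, allow_pickle=False) as archive:
        meta = {}
        seen = set()
        for key in archive.files:
            if key.startswith("__meta__/"):
                meta[key.split("/", 1)[1]] = archive[key]
                continue
            if key not in params:
                raise KeyError(f"checkpoint parameter {key!r} not present in model")
            if params[key].data.shape != archive[key].shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: model {params[key].data.shape}, "
                    f"checkpoint {archive[key].shape}"
                )
            params[key].data = archive[key].astype(np.float64)
            seen.add(key)
        missing = set(params) - seen
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
    return meta
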