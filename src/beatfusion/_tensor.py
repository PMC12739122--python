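"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the beat classifier needs: broadcasted
arithmetic, (batched) matrix multiplication, reductions, shape ops, the
nonlinearities (ReLU, sigmoid, exp/log/pow, softmax), 1-D convolution with
``valid``/``same`` padding, non-overlapping max pooling, and inverted
dropout.  Gradients are accumulated into ``Tensor.grad`` by ``backward()``
over a topologically sorted graph.

All data is float64: the package favours bit-reproducibility and tight
numerical tolerances over raw throughput, and the models it trains are
small enough that this costs little.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "conv1d", "maxpool1d", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward_fn = _backward_fn

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar if grad omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- construction helpers --------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward_fn = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        out._backward_fn = _bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward_fn = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._wrap(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward_fn = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward_fn = _bw
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward_fn = _bw
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward_fn = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward_fn = _bw
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        val = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, 0, None))),
            np.exp(np.clip(self.data, None, 0)) / (1.0 + np.exp(np.clip(self.data, None, 0))),
        )
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward_fn = _bw
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """Elementwise max(x, lo); gradient passes only where x > lo."""
        out = Tensor(np.maximum(self.data, lo), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > lo))

        out._backward_fn = _bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        out._backward_fn = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward_fn = _bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward_fn = _bw
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward_fn = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward_fn = _bw
        return out


# -- free functions ----------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor._wrap(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=tuple(ts),
    )
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward_fn = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with the analytic Jacobian-vector product."""
    x = Tensor._wrap(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * val).sum(axis=axis, keepdims=True)
            x._accumulate(val * (g - dot))

    out._backward_fn = _bw
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: str = "valid") -> Tensor:
    """Batched 1-D convolution (cross-correlation form used throughout deep nets).

    x: (batch, in_channels, length); weight: (out_channels, in_channels, K);
    bias: (out_channels,).  ``valid`` emits length − K + 1 steps; ``same``
    zero-pads symmetrically to preserve length (K must be odd).
    """
    x = Tensor._wrap(x)
    weight = Tensor._wrap(weight)
    K = weight.data.shape[-1]
    if K < 1:
        raise ValueError("kernel must be non-empty")
    if padding == "same":
        if K % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")
        pad = K // 2
        xdata = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    elif padding == "valid":
        pad = 0
        xdata = x.data
    else:
        raise ValueError(f"unknown padding {padding!r}")
    if xdata.shape[-1] < K:
        raise ValueError("input shorter than kernel")
    cols = np.lib.stride_tricks.sliding_window_view(xdata, K, axis=2)  # (B, Cin, Lout, K)
    val = np.einsum("bilk,oik->bol", cols, weight.data, optimize=True)
    if bias is not None:
        bias = Tensor._wrap(bias)
        val = val + bias.data[None, :, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(val, requires_grad=any(p.requires_grad for p in parents), _parents=parents)

    def _bw(g: np.ndarray) -> None:
        if weight.requires_grad:
            weight._accumulate(np.einsum("bilk,bol->oik", cols, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(xdata)
            # scatter each kernel tap's contribution back onto the input
            for k in range(K):
                gx[:, :, k : k + g.shape[-1]] += np.einsum(
                    "bol,oi->bil", g, weight.data[:, :, k], optimize=True
                )
            if pad:
                gx = gx[:, :, pad:-pad]
            x._accumulate(gx)

    out._backward_fn = _bw
    return out


def maxpool1d(x: Tensor, window: int) -> Tensor:
    """Non-overlapping max pooling over the last axis.

    A trailing partial window is pooled as-is, so the output length is
    ceil(L / window).
    """
    x = Tensor._wrap(x)
    if window < 1:
        raise ValueError("pool window must be >= 1")
    L = x.data.shape[-1]
    if L == 0:
        raise ValueError("cannot pool an empty input")
    n_out = -(-L // window)
    pad_to = n_out * window
    padded = x.data
    if pad_to != L:
        pad_width = [(0, 0)] * (x.data.ndim - 1) + [(0, pad_to - L)]
        padded = np.pad(x.data, pad_width, constant_values=-np.inf)
    windows = padded.reshape(*x.data.shape[:-1], n_out, window)
    idx = windows.argmax(axis=-1)
    val = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(val, requires_grad=x.requires_grad, _parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(*x.data.shape[:-1], pad_to)[..., :L]
        x._accumulate(gx)

    out._backward_fn = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: scales kept activations by 1/(1−rate) in train mode."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    if not train or rate == 0.0:
        return x
    x = Tensor._wrap(x)
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * mask, requires_grad=x.requires_grad, _parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward_fn = _bw
    return out
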