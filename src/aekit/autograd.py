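"""A minimal reverse-mode automatic differentiation engine over numpy arrays.

Just enough machinery to train the micro-transformer's adapters and the
contrastive projection head: broadcast-aware elementwise arithmetic, matrix
products, reductions, GELU, and the gather/slice/concat plumbing needed for
attention heads and cross-entropy.  Float64 throughout; no in-place ops.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that numpy broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Callable[[], None] = lambda: None
        self._prev = _prev

    # -- graph -------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.requires_grad:
                node._backward()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = bw
        return out

    # -- reductions & nonlinearities ----------------------------------------
    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        out = Tensor(x * cdf, _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * x**2)
                self._accum(out.grad * (cdf + x * pdf))

        out._backward = bw
        return out

    # -- structural ops ------------------------------------------------------
    def cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[:, start:stop] = out.grad
                self._accum(g)

        out._backward = bw
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """out[i] = self[i, idx[i]] — per-row element pick (for cross-entropy)."""
        idx = np.asarray(idx, dtype=int)
        rows = np.arange(self.data.shape[0])
        out = Tensor(self.data[rows, idx], _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, (rows, idx), out.grad)
                self._accum(g)

        out._backward = bw
        return out

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Row gather (embedding lookup): out[i] = self[idx[i]]."""
        idx = np.asarray(idx, dtype=int)
        out = Tensor(self.data[idx], _prev=(self,))

        def bw() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_cols(parts: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), _prev=tuple(parts))
    offsets = np.cumsum([0] + [p.data.shape[1] for p in parts])

    def bw() -> None:
        for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accum(out.grad[:, a:b])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Composite layers
# ---------------------------------------------------------------------------


def softmax_rows(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Row-wise softmax; an additive mask (e.g. -inf above the diagonal for
    causal attention) is applied as a constant before normalization."""
    z = x + Tensor(mask) if mask is not None else x
    shift = Tensor(z.data.max(axis=-1, keepdims=True))  # constant, detached
    e = (z - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax_rows(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    z = x - shift
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    return z - lse


def layer_norm_rows(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row standardization followed by the learned affine map."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    xhat = centered / ((var + eps) ** 0.5)
    return xhat * gain + bias


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Sum over positions of -log p(target); log-sum-exp stabilized."""
    logp = log_softmax_rows(logits)
    return -logp.gather_rows(targets).sum()


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Standard Adam over an explicit parameter list."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
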