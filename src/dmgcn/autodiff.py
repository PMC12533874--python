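"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is trained on CPU at desk scale (hundreds to a few
thousand spots), so the engine favours clarity over throughput: a :class:`Tensor`
wraps a float64 ``numpy.ndarray``, records the operation that produced it, and
``backward`` walks the graph in reverse topological order accumulating
gradients.  Sparse graph operators (scipy CSR/CSC) enter the graph as constants
through :func:`spmm`.

Every differentiable op is exercised by a central-finite-difference check in
the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln as _gammaln

__all__ = ["Tensor", "tensor", "spmm", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to our reflected operators instead of broadcasting
    # Tensor objects elementwise
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth scales with graph size
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __matmul__(self, other):
        other = tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        out = _make(self.data.T, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.T)
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        mask = (self.data > 0).astype(np.float64)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _make(t, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * (1 - t**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / (2 * r))
        return out

    def softplus(self):
        # log(1+exp(x)) computed stably; derivative is sigmoid(x)
        v = np.logaddexp(0.0, self.data)
        out = _make(v, (self,))
        s = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s)
        return out

    def lgamma(self):
        out = _make(_gammaln(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * digamma(self.data)
        )
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float64)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def tensor(x) -> Tensor:
    """Wrap arrays/scalars as constant tensors; pass tensors through."""
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a: sp.spmatrix, h: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product; gradient flows to ``h`` only."""
    a = a.tocsr()
    out = _make(np.asarray(a @ h.data), (h,))
    at = a.T.tocsr()
    out._backward = lambda g: h.requires_grad and h._accumulate(np.asarray(at @ g))
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform initialised trainable weight matrix."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam optimiser over a list of :class:`Tensor` parameters."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
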