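"""A compact vectorized reverse-mode automatic-differentiation core.

Just enough machinery to train a small encoder-decoder transformer on the
CPU with NumPy: tensors wrapping ndarrays, a handful of differentiable ops
(matmul, broadcasting add/mul, GELU, masked softmax, layer norm, embedding
lookup, fused softmax cross-entropy) and topological backpropagation.
Gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "set_default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype for new tensors (float32 roughly halves step time)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, req, (self, other), bwd if req else None)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self.scale(float(other))
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, req, (self, other), bwd if req else None)

    __rmul__ = __mul__

    def scale(self, c: float) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g * c)

        return Tensor(self.data * c, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def matmul(self, other: "Tensor") -> "Tensor":
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(np.matmul(self.data, other.data), req, (self, other), bwd if req else None)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), self.requires_grad, (self,), bwd if self.requires_grad else None)

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), self.requires_grad, (self,), bwd if self.requires_grad else None)

    # -- neural-net ops ----------------------------------------------------

    def gelu(self) -> "Tensor":
        # tanh approximation, as used by GPT-style stacks
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def bwd(g):
            if self.requires_grad:
                d_inner = c * (1.0 + 3 * 0.044715 * x**2)
                deriv = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * d_inner
                self._accum(g * deriv)

        return Tensor(out, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def softmax(self, additive_mask: Optional[np.ndarray] = None) -> "Tensor":
        """Softmax over the last axis, with an optional additive logit mask."""
        z = self.data if additive_mask is None else self.data + additive_mask
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accum(s * (g - dot))

        return Tensor(s, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gain.data + bias.data
        req = self.requires_grad or gain.requires_grad or bias.requires_grad

        def bwd(g):
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.shape))
            if self.requires_grad:
                n = x.shape[-1]
                gx = g * gain.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                    (gx * xhat).mean(axis=-1, keepdims=True)
                )
                self._accum(term * inv)

        return Tensor(out, req, (self, gain, bias), bwd if req else None)

    def embedding(self, ids: np.ndarray) -> "Tensor":
        """Row lookup: self is the (V, D) table, ids an integer array."""
        ids = np.asarray(ids)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, ids.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accum(acc)

        return Tensor(self.data[ids], self.requires_grad, (self,), bwd if self.requires_grad else None)

    def dropout(self, p: float, rng: Optional[np.random.Generator]) -> "Tensor":
        """Inverted dropout; pass rng=None to disable (inference)."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def add_const(self, c: np.ndarray) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g)

        return Tensor(self.data + c, self.requires_grad, (self,), bwd if self.requires_grad else None)

    def cross_entropy(self, targets: np.ndarray, mask: np.ndarray) -> "Tensor":
        """Mean token-level cross-entropy of (N, V) logits.

        ``targets`` are class indices (N,), ``mask`` selects scored tokens;
        the loss is averaged over the masked-in tokens.
        """
        logits = self.data
        z = logits - logits.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - logsumexp
        n = max(mask.sum(), 1)
        nll = -(logp[np.arange(len(targets)), targets] * mask).sum() / n

        def bwd(g):
            if self.requires_grad:
                p = np.exp(logp)
                p[np.arange(len(targets)), targets] -= 1.0
                self._accum(g * p * (mask[:, None] / n))

        return Tensor(nll, self.requires_grad, (self,), bwd if self.requires_grad else None)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.array(data, dtype=_DEFAULT_DTYPE), requires_grad=True)
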