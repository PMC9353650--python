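"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations a compact vision transformer needs:
broadcasting arithmetic, matrix products, row gathering/stacking, softmax,
layer normalization, GELU, sigmoid, and a numerically stable
binary-cross-entropy-with-logits reduction.  Gradients are accumulated in
float64 and propagated by a topological sweep over the recorded tape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "stack_rows", "concat_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # own the buffer: closures may hand us views or shared arrays
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(gb, b.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    def affine(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Fused x @ W + b for 2-D x, (D_in, D_out) W and (D_out,) b."""
        out_data = self.data @ weight.data + bias.data

        def backward(g):
            self._accum(g @ weight.data.T)
            weight._accum(self.data.T @ g)
            bias._accum(g.sum(axis=0))

        out = self._make(out_data, (self, weight, bias), backward)
        return out

    def split_heads(self, n_heads: int) -> "Tensor":
        """(T, D) -> (n_heads, T, D // n_heads) in a single node."""
        T, D = self.data.shape
        dh = D // n_heads

        def backward(g):
            self._accum(g.transpose(1, 0, 2).reshape(T, D))

        out = self._make(self.data.reshape(T, n_heads, dh).transpose(1, 0, 2),
                         (self,), backward)
        return out

    def merge_heads(self) -> "Tensor":
        """(n_heads, T, dh) -> (T, n_heads * dh) in a single node."""
        h, T, dh = self.data.shape

        def backward(g):
            self._accum(g.reshape(T, h, dh).transpose(1, 0, 2))

        out = self._make(self.data.transpose(1, 0, 2).reshape(T, h * dh),
                         (self,), backward)
        return out

    # -- reshaping and indexing -----------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        def backward(g):
            self._accum(g.reshape(self.data.shape))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        out = self._make(self.data.transpose(*axes), (self,), backward)
        return out

    def gather_rows(self, indices) -> "Tensor":
        """Select rows along axis 0; duplicate indices accumulate gradient."""
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            scatter = np.zeros_like(self.data)
            np.add.at(scatter, idx, g)
            self._accum(scatter)

        out = self._make(self.data[idx], (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        out = self._make(self.data.sum(axis=axis), (self,), backward)
        return out

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    # -- nonlinearities -------------------------------------------------------
    def softmax(self) -> "Tensor":
        """Row-wise softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accum(s * (g - dot))

        out = self._make(s, (self,), backward)
        return out

    def gelu(self) -> "Tensor":
        """Gaussian error linear unit (tanh approximation)."""
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)

        def backward(g):
            sech2 = 1.0 - t * t
            dy = 0.5 * (1.0 + t) + 0.5 * x * sech2 * c * (1.0 + 3 * 0.044715 * x**2)
            self._accum(g * dy)

        out = self._make(y, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        out = self._make(s, (self,), backward)
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize the last axis to zero mean / unit variance, then affine."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        y = gain.data * xhat + bias.data

        def backward(g):
            d = x.shape[-1]
            gx = g * gain.data
            # classic layer-norm backward through mean and variance
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            self._accum(term * inv)
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
            bias._accum(_unbroadcast(g, bias.data.shape))

        out = self._make(y, (self, gain, bias), backward)
        return out

    def bce_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Mean element-wise binary cross-entropy, stable logits form.

        loss = max(x,0) - x*y + log(1 + exp(-|x|)), averaged over all elements.
        """
        x = self.data
        y = np.asarray(targets, dtype=np.float64)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("targets must lie in [0, 1]")
        if y.shape != x.shape:
            raise ValueError(f"target shape {y.shape} != logit shape {x.shape}")
        loss = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))

        def backward(g):
            s = 1.0 / (1.0 + np.exp(-x))
            self._accum(g * (s - y) / x.size)

        out = self._make(loss.mean(), (self,), backward)
        return out

    # -- backward pass --------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free the tape behind us: intermediate grads and graph
                # edges are not needed once a node has propagated
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor along a new first axis."""
    parents = tuple(tensors)
    data = np.stack([t.data for t in parents])
    out = Tensor(data)
    if any(t.requires_grad for t in parents):
        out.requires_grad = True
        out._parents = parents

        def backward(g):
            for i, t in enumerate(parents):
                t._accum(g[i])

        out._backward = backward
    return out


def concat_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    parents = tuple(tensors)
    data = np.concatenate([t.data for t in parents], axis=0)
    out = Tensor(data)
    if any(t.requires_grad for t in parents):
        out.requires_grad = True
        out._parents = parents

        def backward(g):
            start = 0
            for t in parents:
                n = t.data.shape[0]
                t._accum(g[start:start + n])
                start += n

        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
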