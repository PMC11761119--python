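"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the classifier needs: broadcasting
arithmetic, batched matmul, reshape/transpose/roll/stack, reductions,
softmax, GELU, layer/batch normalisation, a 3x3 depthwise convolution and
cross-entropy.  Gradients are accumulated on a tape and released by a
topological backward pass.  Everything is float32 unless the caller says
otherwise.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "stack", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def pow(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(src_shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def roll(self, shift: Sequence[int], axis: Sequence[int]):
        shift = tuple(shift)
        axis = tuple(axis)

        def backward(g):
            if self.requires_grad:
                self._accum(np.roll(g, tuple(-s for s in shift), axis))

        return self._make(np.roll(self.data, shift, axis), (self,), backward)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities --------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # exact (erf) form; derivative is Phi(x) + x * phi(x)
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = (x * cdf).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accum(g * (cdf + x * pdf))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then affine (gamma, beta)."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * weight.data + bias.data

        def backward(g):
            n = x.shape[-1]
            if weight.requires_grad:
                red = tuple(range(g.ndim - 1))
                weight._accum((g * xhat).sum(axis=red))
            if bias.requires_grad:
                red = tuple(range(g.ndim - 1))
                bias._accum(g.sum(axis=red))
            if self.requires_grad:
                gx = g * weight.data
                t1 = gx.sum(axis=-1, keepdims=True)
                t2 = (gx * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv / n * (n * gx - t1 - xhat * t2))

        return self._make(out_data, (self, weight, bias), backward)

    # ---- gather ----------------------------------------------------------
    def gather_rows(self, index: np.ndarray):
        """out[k] = self[index[k]] along axis 0 (used for position-bias tables)."""
        index = np.asarray(index)

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accum(acc)

        return self._make(self.data[index], (self,), backward)

    # ---- convolution -----------------------------------------------------
    def depthwise_conv3x3(self, weight: "Tensor"):
        """Per-channel 3x3 convolution with zero padding 1.

        self: (B, H, W, C); weight: (3, 3, C).
        """
        x = self.data
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out_data = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                out_data += weight.data[i, j] * xp[:, i : i + H, j : j + W, :]

        def backward(g):
            if weight.requires_grad:
                gw = np.zeros_like(weight.data)
                for i in range(3):
                    for j in range(3):
                        gw[i, j] = (g * xp[:, i : i + H, j : j + W, :]).sum(axis=(0, 1, 2))
                weight._accum(gw)
            if self.requires_grad:
                gp = np.zeros_like(xp)
                for i in range(3):
                    for j in range(3):
                        gp[:, i : i + H, j : j + W, :] += weight.data[i, j] * g
                self._accum(gp[:, 1 : 1 + H, 1 : 1 + W, :])

        return self._make(out_data, (self, weight), backward)

    # ---- backward driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:  # iterative topological sort; graphs are deep
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen and p._backward is not None]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                stack_.pop()
                if node._backward is not None:
                    topo.append(node)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            node._backward(node.grad)
            if node is not self:
                node.grad = None  # free intermediate grads
            node._backward = None
            node._prev = ()


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def backward(g):
            parts = np.split(g, len(tensors), axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(np.squeeze(p, axis=axis))

        out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch; labels are integer class ids."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    out_data = np.float32(nll.mean())

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    out = Tensor(out_data)
    if logits.requires_grad:
        out.requires_grad = True
        out._prev = (logits,)
        out._backward = backward
    return out
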