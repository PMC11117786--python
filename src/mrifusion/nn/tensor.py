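"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the fusion network needs: broadcast
arithmetic, matmul, dense and depthwise 2D convolution, batch
normalization, SiLU/sigmoid, reductions, reshape/concat, and a
numerically stable binary cross-entropy on logits.  Gradients are
accumulated by topological-order backward passes, micrograd-style, but
array-valued throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------------
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

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.mean(axis=axis, keepdims=keepdims)
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape) / n)

        return self._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """Dense NCHW convolution (cross-correlation), no bias.

        weight: (C_out, C_in, k, k).
        """
        x, w = self.data, weight.data
        n, c_in, _, _ = x.shape
        c_out, c_in_w, k, _ = w.shape
        if c_in != c_in_w:
            raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_in_w}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        # patches: (N, C, H_out, W_out, k, k)
        patches = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        out_data = np.einsum("nchwij,ocij->nohw", patches, w, optimize=True)
        h_out, w_out = out_data.shape[2:]

        def backward(g):
            if weight.requires_grad:
                gw = np.einsum("nohw,nchwij->ocij", g, patches, optimize=True)
                weight._accum(gw)
            if self.requires_grad:
                gx = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        t = np.einsum("nohw,oc->nchw", g, w[:, :, i, j], optimize=True)
                        gx[:, :, i : i + stride * h_out : stride,
                           j : j + stride * w_out : stride] += t
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        return self._make(out_data, (self, weight), backward)

    def dwconv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """Depthwise NCHW convolution, one k×k filter per channel.

        weight: (C, k, k).
        """
        x, w = self.data, weight.data
        c = x.shape[1]
        if w.shape[0] != c:
            raise ValueError(f"dwconv2d channel mismatch: input {c}, weight {w.shape[0]}")
        k = w.shape[1]
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        patches = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        out_data = np.einsum("nchwij,cij->nchw", patches, w, optimize=True)
        h_out, w_out = out_data.shape[2:]

        def backward(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nchw,nchwij->cij", g, patches, optimize=True))
            if self.requires_grad:
                gx = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gx[:, :, i : i + stride * h_out : stride,
                           j : j + stride * w_out : stride] += g * w[:, i, j][None, :, None, None]
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        return self._make(out_data, (self, weight), backward)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", mean: np.ndarray,
                  var: np.ndarray, eps: float = 1e-5, training: bool = False) -> "Tensor":
        """Channel-wise normalization over (N, H, W) of an NCHW tensor.

        In training mode `mean`/`var` must be the batch statistics; in
        eval mode they are the running statistics (treated as constants).
        """
        x = self.data
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if not self.requires_grad:
                return
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if not training:
                self._accum(g * gi)
                return
            m = x.shape[0] * x.shape[2] * x.shape[3]
            gxhat = g * gamma.data[None, :, None, None]
            t1 = gxhat.sum(axis=(0, 2, 3))
            t2 = np.einsum("nchw,nchw->c", gxhat, xhat, optimize=True)
            gx = (inv[None, :, None, None] / m) * (
                m * gxhat - t1[None, :, None, None] - xhat * t2[None, :, None, None]
            )
            self._accum(gx)

        return self._make(out_data, (self, gamma, beta), backward)

    def global_avg_pool(self) -> "Tensor":
        """NCHW -> (N, C) spatial mean."""
        return self.mean(axis=(2, 3))

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, differentiably."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits, numerically stable.

    loss = mean( max(s,0) - s*y + log(1 + exp(-|s|)) ).
    """
    s = logits.data
    y = np.asarray(targets, dtype=np.float32).reshape(s.shape)
    per = np.maximum(s, 0.0) - s * y + np.log1p(np.exp(-np.abs(s)))
    out_data = per.mean()

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-s))
            logits._accum(g * (sig - y) / s.size)

    out = Tensor(out_data)
    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)
        out._backward = backward
    return out
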