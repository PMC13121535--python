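"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network, its training loops, the Fisher-information
estimates and the quadratic consolidation penalties all need gradients of
scalar losses with respect to every trainable array.  This module provides
a small dynamically-built tape: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure, and ``backward()`` walks the
graph in reverse topological order accumulating gradients.

Only the operations the network actually uses are implemented: broadcasted
arithmetic, (batched) matmul, reductions, shape ops, softmax, GELU, log,
exp, abs, 2-D convolution (stride 1, zero same-padding) via im2col,
depthwise convolution, and zero-dilation for transposed-convolution
upsampling.  Everything runs in float64 for the benefit of finite-difference
gradient checks.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concatenate", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims numpy prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=tuple(p for p in parents if p.requires_grad),
                      _backward=backward if req else None)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        # reverse topological order
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))
        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def pow(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))
        return Tensor._make(out_data, (self,), bw)

    __pow__ = pow

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)
        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)
        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        out_data = np.abs(self.data)

        def bw(g):
            self._accum(g * np.sign(self.data))
        return Tensor._make(out_data, (self,), bw)

    def gelu(self):
        """Exact GELU: 0.5·x·(1+erf(x/√2)); d/dx = Φ(x) + x·φ(x)."""
        x = self.data
        phi_cdf = 0.5 * (1.0 + _sp.erf(x / math.sqrt(2.0)))
        out_data = x * phi_cdf

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            self._accum(g * (phi_cdf + x * pdf))
        return Tensor._make(out_data, (self,), bw)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(old_shape))
        return Tensor._make(out_data, (self,), bw)

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accum(g.transpose(inv))
        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor._make(out_data, (self,), bw)

    # -- nonlinear structured ops -----------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * s)
        return Tensor._make(s, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def bw(g):
            self._accum(g - s * g.sum(axis=axis, keepdims=True))
        return Tensor._make(out, (self,), bw)

    # -- convolution -------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               padding: int = 1):
        """Stride-1 zero-padded 2-D convolution.

        self: (B, C, H, W); weight: (O, C, kh, kw); bias: (O,).
        Output spatial size = H + 2·padding − kh + 1 (``padding=(k−1)//2``
        gives same-size output for odd kernels).
        """
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
        cols, (Ho, Wo) = _im2col(x, kh, kw, padding)  # (B, Ho*Wo, C*kh*kw)
        w_flat = w.reshape(O, -1)
        out = cols @ w_flat.T                           # (B, Ho*Wo, O)
        if bias is not None:
            out = out + bias.data
        out_data = out.transpose(0, 2, 1).reshape(B, O, Ho, Wo)

        def bw(g):
            g_flat = np.ascontiguousarray(
                g.reshape(B, O, Ho * Wo).transpose(0, 2, 1))      # (B,HW,O)
            if weight.requires_grad:
                gw = g_flat.reshape(-1, O).T @ cols.reshape(-1, C * kh * kw)
                weight._accum(gw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g_flat.sum(axis=(0, 1)))
            if self.requires_grad:
                dcols = g_flat @ w_flat                 # (B,HW,C*kh*kw)
                self._accum(_col2im(dcols, x.shape, kh, kw, padding, Ho, Wo))
        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
                         padding: int = 1):
        """Per-channel 2-D convolution. weight: (C, kh, kw); bias: (C,)."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError("depthwise kernel count must equal channels")
        cols, (Ho, Wo) = _im2col_depthwise(x, kh, kw, padding)  # (B,C,HW,k2)
        w_flat = w.reshape(C, -1)
        out = (cols @ w_flat[None, :, :, None])[..., 0]         # (B,C,HW)
        if bias is not None:
            out = out + bias.data[None, :, None]
        out_data = out.reshape(B, C, Ho, Wo)

        def bw(g):
            g_ = g.reshape(B, C, Ho * Wo)
            if weight.requires_grad:
                gw = (g_[:, :, None, :] @ cols).sum(axis=0)[:, 0]
                weight._accum(gw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g_.sum(axis=(0, 2)))
            if self.requires_grad:
                dcols = g_[..., None] * w_flat[None, :, None, :]
                # fold channel into batch and reuse dense col2im with C=1
                dcols_b = dcols.reshape(B * C, Ho * Wo, kh * kw)
                gx = _col2im(dcols_b, (B * C, 1, H, W), kh, kw, padding, Ho, Wo)
                self._accum(gx.reshape(B, C, H, W))
        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def dilate2(self):
        """Insert zeros between pixels: (…, H, W) → (…, 2H, 2W), input at
        even indices.  The zero-insertion half of a stride-2 transposed
        convolution."""
        x = self.data
        out_shape = x.shape[:-2] + (2 * x.shape[-2], 2 * x.shape[-1])
        out_data = np.zeros(out_shape, dtype=x.dtype)
        out_data[..., ::2, ::2] = x

        def bw(g):
            self._accum(g[..., ::2, ::2])
        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    return Tensor._make(out_data, tensors, bw)


# -- im2col helpers --------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    Ho, Wo = win.shape[2], win.shape[3]
    # (B, C, Ho, Wo, kh, kw) -> (B, Ho*Wo, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
    return np.ascontiguousarray(cols), (Ho, Wo)


def _im2col_depthwise(x: np.ndarray, kh: int, kw: int, pad: int):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.reshape(B, C, Ho * Wo, kh * kw)
    return np.ascontiguousarray(cols), (Ho, Wo)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, pad: int,
            Ho: int, Wo: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add column gradients back to image."""
    B, C, H, W = x_shape
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    d = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + Ho, j:j + Wo] += d[:, :, :, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp
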