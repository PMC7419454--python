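"""Minimal reverse-mode automatic differentiation on numpy arrays.

Real-valued tensors only; the complex arithmetic of the speckle transform is
hidden inside a single fused op (:func:`speckle_transform`) whose backward
pass is derived by hand (Wirtinger calculus reduces to adjoint FFTs because
both transforms are linear).  Bilinear polar warps enter as sparse linear
maps whose adjoint is the transpose.

The op set is exactly what the GAN needs — no more.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .._conv import conv2d_backward, conv2d_forward
from ..speckle import spectral_window_profile, spectral_window_profile_grad

__all__ = ["Tensor", "concat", "speckle_transform", "sparse_linear"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over broadcast dimensions back to ``shape``."""
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
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data, name: str = "") -> "Tensor":
        return Tensor(data, requires_grad=True, name=name)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data: np.ndarray, prev: tuple["Tensor", ...], backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = prev
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None if node._prev else node.grad  # free intermediates

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data**exponent, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    # -- reductions and shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = self._make(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = self._make(root, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / root)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the range."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * inside)

        out._backward = backward
        return out

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- structured ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, pad: int = 0):
        bdat = bias.data if bias is not None else None
        out_data = conv2d_forward(self.data, weight.data, bdat, stride, pad)
        prev = (self, weight) if bias is None else (self, weight, bias)
        out = self._make(out_data, prev, None)

        def backward(g):
            dx, dw, db = conv2d_backward(g, self.data, weight.data, stride, pad)
            if self.requires_grad:
                self._accum(dx)
            if weight.requires_grad:
                weight._accum(dw)
            if bias is not None and bias.requires_grad:
                bias._accum(db)

        out._backward = backward
        return out

    def upsample_nearest2x(self):
        """(n, c, h, w) -> (n, c, 2h, 2w) by pixel repetition."""
        data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = self._make(data, (self,), None)

        def backward(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                self._accum(
                    g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                )

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if not out.requires_grad:
        return out
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._prev = tuple(tensors)
    out._backward = backward
    return out


def speckle_transform(
    x: Tensor, d: Tensor, phases: np.ndarray, softness: float
) -> Tensor:
    """Differentiable speckle transform over the trailing two axes.

    ``out = |IFFT2(FFT2(x * exp(j*phases)) * W(d))|`` with a soft square
    spectral window of edge length ``d`` (scalar tensor).  Gradients flow to
    both ``x`` and ``d``; ``phases`` is a constant array broadcastable to
    ``x``.  The backward pass uses the adjoint FFT identities
    ``adj(ifft2) = fft2 / N`` and ``adj(fft2) = N * ifft2`` under the real
    inner product.
    """
    h, w = x.data.shape[-2], x.data.shape[-1]
    n_total = h * w
    dval = float(d.data)
    kr = np.arange(h, dtype=float) - h // 2
    kc = np.arange(w, dtype=float) - w // 2
    pr = spectral_window_profile(dval, kr, softness)
    pc = spectral_window_profile(dval, kc, softness)
    win = np.fft.ifftshift(np.outer(pr, pc))

    carrier = np.exp(1j * phases)
    field = x.data * carrier
    spec_in = np.fft.fft2(field, axes=(-2, -1))
    spec_filtered = spec_in * win
    u = np.fft.ifft2(spec_filtered, axes=(-2, -1))
    mag = np.abs(u)
    out = Tensor(mag)
    out.requires_grad = x.requires_grad or d.requires_grad
    if not out.requires_grad:
        return out

    def backward(g):
        safe = np.maximum(mag, 1e-12)
        g_u = g * u / safe                      # dL/dU as a complex array
        g_spec = np.fft.fft2(g_u, axes=(-2, -1)) / n_total
        if d.requires_grad:
            if softness <= 0:
                raise ValueError("d is not differentiable for a hard window")
            g_win = np.real(g_spec * np.conj(spec_in))
            if g_win.ndim > 2:
                g_win = g_win.sum(axis=tuple(range(g_win.ndim - 2)))
            g_win_c = np.fft.fftshift(g_win)
            dpr = spectral_window_profile_grad(dval, kr, softness)
            dpc = spectral_window_profile_grad(dval, kc, softness)
            dwin_dd = np.outer(dpr, pc) + np.outer(pr, dpc)
            d._accum(np.array(np.sum(g_win_c * dwin_dd)).reshape(d.data.shape))
        if x.requires_grad:
            g_y = g_spec * win
            g_field = np.fft.ifft2(g_y, axes=(-2, -1)) * n_total
            x._accum(np.real(g_field * np.conj(carrier)))

    out._prev = (x, d)
    out._backward = backward
    return out


def sparse_linear(x: Tensor, matrix: sp.csr_matrix, out_hw: tuple[int, int]) -> Tensor:
    """Apply a sparse linear map to the trailing two axes of (n, c, h, w).

    Used for bilinear polar warps; the adjoint is the matrix transpose.
    """
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n * c, h * w)
    out_flat = flat @ matrix.T
    out_data = out_flat.reshape(n, c, *out_hw)
    out = Tensor(out_data)
    out.requires_grad = x.requires_grad
    if not out.requires_grad:
        return out

    def backward(g):
        g_flat = g.reshape(n * c, -1)
        x._accum((g_flat @ matrix).reshape(x.data.shape))

    out._prev = (x,)
    out._backward = backward
    return out
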