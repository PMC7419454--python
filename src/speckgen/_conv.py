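"""2-D convolution (cross-correlation) with forward and backward passes,
shared by the desk embedder and the network layers.

Implemented as a shift-and-accumulate over kernel taps: each (i, j) tap is
one BLAS tensordot between the kernel slice and a strided view of the
padded input, which avoids im2col's large scattered copies.

Layout: batched tensors are (n, c, h, w); kernels are (c_out, c_in, kh, kw).
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv2d_forward", "conv2d_backward"]


def _pad(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _out_size(h: int, kh: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - kh) // stride + 1


def conv2d_forward(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None,
    stride: int = 1, pad: int = 0,
) -> np.ndarray:
    """Cross-correlate (n, c_in, h, w) with (c_out, c_in, kh, kw)."""
    n, ci, h, w = x.shape
    co, _, kh, kw = weight.shape
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    xp = _pad(x, pad)
    out = np.zeros((n, co, oh, ow))
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            # (n, ci, oh, ow) x (co, ci) -> (n, oh, ow, co)
            out += np.tensordot(xs, weight[:, :, i, j], axes=([1], [1])).transpose(
                0, 3, 1, 2
            )
    if bias is not None:
        out += bias[None, :, None, None]
    return out


def conv2d_backward(
    grad_out: np.ndarray, x: np.ndarray, weight: np.ndarray,
    stride: int = 1, pad: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dweight, dbias) of :func:`conv2d_forward`."""
    n, ci, h, w = x.shape
    co, _, kh, kw = weight.shape
    _, _, oh, ow = grad_out.shape
    xp = _pad(x, pad)
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(weight)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            # dW[o, c] = sum_{n, p} g[n, o, p] * xs[n, c, p]
            dw[:, :, i, j] = np.tensordot(grad_out, xs, axes=([0, 2, 3], [0, 2, 3]))
            # dx tap: (n, oh, ow, ci)
            contrib = np.tensordot(grad_out, weight[:, :, i, j], axes=([1], [0]))
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                contrib.transpose(0, 3, 1, 2)
            )
    db = grad_out.sum(axis=(0, 2, 3))
    dx = dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp
    return dx, dw, db
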