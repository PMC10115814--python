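"""Structured operations: convolution, pooling and bilinear resampling.

Convolution is evaluated as a strided-view contraction (im2col without the
copy); its input gradient is computed as the standard transposed convolution
(zero-stuffed output gradient correlated with the flipped kernel), so no
scatter-add is needed on the hot path.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "interpolate_bilinear"]


def _windows(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """(N,C,H,W) -> view (N,C,Ho,Wo,kh,kw) of dilated, strided patches."""
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    return win


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, kernel (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, "
                         f"kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    win = _windows(xp, kh, kw, stride, dilation)
    out = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if weight.requires_grad:
            gw = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            n, _, ho, wo = g.shape
            hp, wp = xp.shape[2], xp.shape[3]
            # zero-stuff the output gradient back to stride 1
            gs = np.zeros((n, cout, hp - (kh - 1) * dilation,
                           wp - (kw - 1) * dilation), dtype=g.dtype)
            gs[:, :, ::stride, ::stride] = g
            pad = (kh - 1) * dilation
            padw = (kw - 1) * dilation
            gp = np.pad(gs, ((0, 0), (0, 0), (pad, pad), (padw, padw)))
            wflip = weight.data[:, :, ::-1, ::-1]
            gwin = _windows(gp, kh, kw, 1, dilation)
            gx = np.einsum("nohwij,ocij->nchw", gwin, wflip, optimize=True)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx)

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling; padding (if any) uses -inf so it never wins the max."""
    stride = stride or kernel
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)), constant_values=-np.inf)
    win = sliding_window_view(xd, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros_like(xd)
        ky, kx_ = np.divmod(arg, kernel)
        ii = np.arange(ho)[None, None, :, None] * stride + ky
        jj = np.arange(wo)[None, None, None, :] * stride + kx_
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gx, (nn, cc, ii, jj), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accumulate(gx)

    return Tensor._make(out, (x,), bw)


@lru_cache(maxsize=64)
def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (align_corners=False convention)."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    mat = np.zeros((n_out, n_in))
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def interpolate_bilinear(x: Tensor, scale_factor: float) -> Tensor:
    """Bilinear resize of an NCHW tensor (align_corners=False)."""
    n, c, h, w = x.shape
    ho, wo = int(round(h * scale_factor)), int(round(w * scale_factor))
    ah = _resize_matrix(h, ho).astype(x.dtype)
    aw = _resize_matrix(w, wo).astype(x.dtype)
    out = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def bw(g):
        gx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
        x._accumulate(gx)

    return Tensor._make(out, (x,), bw)
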