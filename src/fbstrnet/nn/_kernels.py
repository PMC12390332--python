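"""Numba-compiled inner loops for the convolution layers.

These kernels fuse padding with the patch gather/scatter so the hot path
avoids the intermediate padded arrays and transpose copies a pure-numpy
im2col needs. Matrix products themselves stay in BLAS.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def im2col(x, kh, kw, stride, pad):
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo), zero-padded borders."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    col = np.zeros((n, c * kh * kw, ho * wo), dtype=x.dtype)
    for b in range(n):
        for ch in range(c):
            for i in range(kh):
                for j in range(kw):
                    krow = (ch * kh + i) * kw + j
                    for oh in range(ho):
                        ih = oh * stride + i - pad
                        if ih < 0 or ih >= h:
                            continue
                        base = oh * wo
                        for ow in range(wo):
                            iw = ow * stride + j - pad
                            if 0 <= iw < w:
                                col[b, krow, base + ow] = x[b, ch, ih, iw]
    return col


@njit(cache=True, fastmath=True)
def col2im(dcol, n, c, h, w, kh, kw, stride, pad, ho, wo):
    """Scatter-add the (N, C*kh*kw, Ho*Wo) gradient back to (N,C,H,W)."""
    dx = np.zeros((n, c, h, w), dtype=dcol.dtype)
    for b in range(n):
        for ch in range(c):
            for i in range(kh):
                for j in range(kw):
                    krow = (ch * kh + i) * kw + j
                    for oh in range(ho):
                        ih = oh * stride + i - pad
                        if ih < 0 or ih >= h:
                            continue
                        base = oh * wo
                        for ow in range(wo):
                            iw = ow * stride + j - pad
                            if 0 <= iw < w:
                                dx[b, ch, ih, iw] += dcol[b, krow, base + ow]
    return dx


@njit(cache=True, fastmath=True)
def depthwise_forward(x, weight, stride, pad):
    """x (N,C,H,W), weight (C,kh,kw) -> (N,C,Ho,Wo)."""
    n, c, h, w = x.shape
    _, kh, kw = weight.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    out = np.zeros((n, c, ho, wo), dtype=x.dtype)
    for b in range(n):
        for ch in range(c):
            for oh in range(ho):
                for ow in range(wo):
                    acc = x.dtype.type(0.0)
                    for i in range(kh):
                        ih = oh * stride + i - pad
                        if ih < 0 or ih >= h:
                            continue
                        for j in range(kw):
                            iw = ow * stride + j - pad
                            if 0 <= iw < w:
                                acc += x[b, ch, ih, iw] * weight[ch, i, j]
                    out[b, ch, oh, ow] = acc
    return out


@njit(cache=True, fastmath=True)
def depthwise_backward(x, weight, g, stride, pad):
    """Gradients (dx, dw) of the depthwise convolution."""
    n, c, h, w = x.shape
    _, kh, kw = weight.shape
    ho, wo = g.shape[2], g.shape[3]
    dx = np.zeros_like(x)
    dw = np.zeros_like(weight)
    for b in range(n):
        for ch in range(c):
            for oh in range(ho):
                for ow in range(wo):
                    gv = g[b, ch, oh, ow]
                    for i in range(kh):
                        ih = oh * stride + i - pad
                        if ih < 0 or ih >= h:
                            continue
                        for j in range(kw):
                            iw = ow * stride + j - pad
                            if 0 <= iw < w:
                                dx[b, ch, ih, iw] += gv * weight[ch, i, j]
                                dw[ch, i, j] += gv * x[b, ch, ih, iw]
    return dx, dw
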