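"""Functional ops: convolutions, pooling, normalization, and the
element-wise helpers that the box-loss math shares with the plain-numpy
analysis path (see :mod:`fbstrnet.boxes`)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels as _k
from .tensor import Tensor, as_tensor

pi = float(np.pi)


# --------------------------------------------------------------- elementwise
# Free-function forms so the SIoU/CIoU math can be written once against a
# namespace that is either numpy or this module.
def exp(x):
    return as_tensor(x).exp()


def log(x):
    return as_tensor(x).log()


def sqrt(x):
    return as_tensor(x).sqrt()


def sin(x):
    return as_tensor(x).sin()


def arcsin(x):
    return as_tensor(x).arcsin()


def arctan(x):
    return as_tensor(x).arctan()


def abs(x):  # noqa: A001 - mirrors numpy namespace
    return as_tensor(x).abs()


def clip(x, lo, hi):
    return as_tensor(x).clip(lo, hi)


def sigmoid(x):
    return as_tensor(x).sigmoid()


def stop_gradient(x):
    return as_tensor(x).detach()


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    mask = (a.data >= b.data).astype(np.result_type(a.data, b.data))

    def bw(g):
        if a.requires_grad:
            from .tensor import _unbroadcast

            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            from .tensor import _unbroadcast

            b._accumulate(_unbroadcast(g * (1.0 - mask), b.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), bw)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    mask = (a.data <= b.data).astype(np.result_type(a.data, b.data))

    def bw(g):
        if a.requires_grad:
            from .tensor import _unbroadcast

            a._accumulate(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            from .tensor import _unbroadcast

            b._accumulate(_unbroadcast(g * (1.0 - mask), b.shape))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), bw)


def where(cond, a, b):
    cond = np.asarray(cond)
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        from .tensor import _unbroadcast

        if a.requires_grad:
            a._accumulate(_unbroadcast(g * cond, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~cond), b.shape))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), bw)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Numerically stable binary cross-entropy on logits, mean-reduced.

    max(x,0) - x*t + log(1 + exp(-|x|))
    """
    x = as_tensor(logits)
    t = as_tensor(targets)
    loss = maximum(x, 0.0) - x * t + log(exp(-abs(x)) + 1.0)
    return loss.mean()


# -------------------------------------------------------------- convolutions
def _patches(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> strided window view (N,C,Ho,Wo,kh,kw)."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW, via im2col + GEMM."""
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    o, _, kh, kw = wd.shape
    col = _k.im2col(xd, kh, kw, stride, padding)  # (N, C*kh*kw, L)
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    w2 = wd.reshape(o, -1)
    out = (w2 @ col).reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    def bw(g):
        g2 = np.ascontiguousarray(g.reshape(n, o, ho * wo))
        if weight.requires_grad:
            # batched per-image GEMMs summed over the batch
            dw = np.matmul(g2, col.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(wd.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.matmul(w2.T, g2)  # (N, K, L)
            x._accumulate(_k.col2im(np.ascontiguousarray(dcol), n, c, h, w,
                                    kh, kw, stride, padding, ho, wo))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise convolution: weight (C,1,kh,kw), one filter per channel."""
    xd, wd = x.data, weight.data
    c = xd.shape[1]
    w3 = np.ascontiguousarray(wd.reshape(c, wd.shape[2], wd.shape[3]))
    out = _k.depthwise_forward(xd, w3, stride, padding)
    if bias is not None:
        out = out + bias.data.reshape(1, c, 1, 1)

    def bw(g):
        g = np.ascontiguousarray(g)
        dx, dw = _k.depthwise_backward(xd, w3, g, stride, padding)
        if weight.requires_grad:
            weight._accumulate(dw.reshape(wd.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    xd = x.data
    n, c, _, _ = xd.shape
    xpad = np.pad(
        xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = _patches(xpad, kernel, kernel, stride)
    ho, wo = win.shape[2], win.shape[3]
    wf = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = wf.argmax(axis=-1)
    out = np.take_along_axis(wf, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros_like(xpad)
        ni, ci, hi, wi = np.indices((n, c, ho, wo))
        rows = hi * stride + idx // kernel
        cols = wi * stride + idx % kernel
        np.add.at(dxp, (ni, ci, rows, cols), g)
        hp, wp = xpad.shape[2], xpad.shape[3]
        x._accumulate(
            dxp[:, :, padding : hp - padding or None, padding : wp - padding or None]
        )

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.03,
               eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization for NCHW with running statistics.

    Running buffers are plain arrays updated in place (not differentiated).
    Momentum/eps defaults follow the YOLOv5 convention.
    """
    xd = x.data
    n, c, h, w = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n * h * w / max(n * h * w - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            k = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
            if training:
                m = n * h * w
                gsum = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                x._accumulate(k * (g - gsum / m - xhat * gx / m))
            else:
                x._accumulate(k * g)

    return Tensor._make(out, (x, gamma, beta), bw)
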