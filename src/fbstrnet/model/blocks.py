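"""Building blocks of the detector: standard YOLOv5 Conv/C3/SPPF and their
Ghost counterparts.

A Ghost module halves the dense computation of a convolution: a primary
convolution produces half of the output channels ("intrinsic" features)
and a cheap 5x5 depthwise convolution derives the other half ("ghost"
features) from them; the two halves are concatenated. For odd output
widths the intrinsic half is rounded up.
"""

from __future__ import annotations

from .. import nn
from ..nn import functional as F


def autopad(kernel: int) -> int:
    return kernel // 2


class Conv(nn.Module):
    """Conv2d (no bias) + BatchNorm + optional SiLU: the YOLOv5 'Conv'."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, act: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, autopad(k) if p is None else p,
                              groups=g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.silu() if self.act else x


class Bottleneck(nn.Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """CSP bottleneck with three convolutions."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c1, c_, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = nn.Sequential(*(Bottleneck(c_, c_, shortcut) for _ in range(n)))

    def forward(self, x):
        return self.cv3(F.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        p = autopad(self.k)
        y1 = F.max_pool2d(x, self.k, 1, p)
        y2 = F.max_pool2d(y1, self.k, 1, p)
        y3 = F.max_pool2d(y2, self.k, 1, p)
        return self.cv2(F.concat([x, y1, y2, y3], axis=1))


class GhostConv(nn.Module):
    """Ghost convolution: dense primary half + cheap depthwise ghost half."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, act: bool = True):
        super().__init__()
        if c1 <= 0 or c2 <= 0:
            raise ValueError(f"channel counts must be positive, got {c1}->{c2}")
        c_ = (c2 + 1) // 2  # intrinsic half, rounded up for odd widths
        self.ghost = c2 - c_
        self.cv1 = Conv(c1, c_, k, s, act=act)
        self.cv2 = Conv(c_, c_, 5, 1, g=c_, act=act)  # cheap linear operation

    def forward(self, x):
        y = self.cv1(x)
        g = self.cv2(y)
        if self.ghost != self.cv1.conv.out_ch:
            g = g[:, : self.ghost]
        return F.concat([y, g], axis=1)


class GhostBottleneck(nn.Module):
    """Two stacked ghost convolutions with a residual connection."""

    def __init__(self, c1: int, c2: int):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = GhostConv(c1, c_, 1, 1)
        self.cv2 = GhostConv(c_, c2, 1, 1, act=False)
        self.add = c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3Ghost(nn.Module):
    """C3 block whose inner bottlenecks are rebuilt from Ghost modules."""

    def __init__(self, c1: int, c2: int, n: int = 1):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c1, c_, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = nn.Sequential(*(GhostBottleneck(c_, c_) for _ in range(n)))

    def forward(self, x):
        return self.cv3(F.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


def build_ghost_module(in_channels: int, out_channels: int, kernel: int = 1) -> GhostConv:
    """Standalone Ghost module constructor (intrinsic + ghost = out_channels)."""
    return GhostConv(in_channels, out_channels, kernel)
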