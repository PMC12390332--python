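"""FBStrNet detector assembly.

The skeleton is the YOLOv5-s layer table (depth multiple 0.33, width
multiple 0.50): a strided backbone emitting feature taps at strides
8/16/32, a PANet neck, and an anchor-based prediction head. Two
substitutions define the model:

* ``ghost=True`` replaces the four strided backbone convolutions after
  the stem with GhostConv and the four backbone C3 blocks with C3Ghost
  (the neck is left untouched);
* ``decoupled=True`` replaces the coupled 1x1 prediction convolutions
  with a per-level decoupled head: a 1x1 channel-reducing stem, then two
  parallel branches of two stacked 3x3 convolutions for classification
  and box regression, with an IoU/objectness branch appended to the
  regression branch.

Raw head output layout is ``(N, anchors, H, W, 4+1+nc)`` per level with
channels ordered (x, y, w, h, obj, classes...), shared by the loss and
the decoder regardless of head style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .. import nn
from ..nn import functional as F
from .blocks import C3, C3Ghost, Conv, GhostConv, SPPF

# YOLOv5 default anchor shapes (pixels at 640 input), three per level.
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),       # stride 8
    ((30, 61), (62, 45), (59, 119)),      # stride 16
    ((116, 90), (156, 198), (373, 326)),  # stride 32
)

STRIDES = (8, 16, 32)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(math.ceil(x / divisor) * divisor))


@dataclass
class ArchitectureConfig:
    """Structural hyperparameters of the detector.

    ``head_hidden_channels`` is the decoupled-head branch width. The
    published description gives a nominal 256 before width scaling; the
    default here (124) is the effective width pinned by the published
    parameter budgets of the ablation variants.
    """

    num_classes: int = 12
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    head_hidden_channels: int = 124
    theta: float = 4.0
    loss_name: str = "SIoU"
    decoupled: bool = True
    ghost: bool = True

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValueError("depth/width multiples must be positive")
        if self.loss_name not in ("CIoU", "SIoU"):
            raise ValueError(f"loss_name must be CIoU or SIoU, got {self.loss_name!r}")
        anchors = np.asarray(self.anchors, dtype=np.float64)
        if anchors.shape != (3, 3, 2) or np.any(anchors <= 0):
            raise ValueError("anchors must be 3 scales x 3 positive (w, h) pairs")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")

    @property
    def na(self) -> int:
        return len(self.anchors[0])

    def scaled_anchors(self) -> np.ndarray:
        """Anchor shapes in pixels at the configured input size (reference 640)."""
        return np.asarray(self.anchors, dtype=np.float64) * (self.input_size / 640.0)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["anchors"] = [[list(map(float, a)) for a in lvl] for lvl in self.anchors]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "anchors" in d:
            d["anchors"] = tuple(tuple(tuple(a) for a in lvl) for lvl in d["anchors"])
        return cls(**d)


@dataclass
class ParameterReport:
    """Trainable-parameter budget of a constructed detector.

    ``millions`` is the budget in millions truncated to one decimal, the
    convention used for reporting model size throughout this package.
    """

    total: int
    by_component: dict = field(default_factory=dict)
    millions: float = 0.0

    @staticmethod
    def millions_of(total: int) -> float:
        return math.floor(total / 1e5) / 10.0


class Detect(nn.Module):
    """Coupled YOLOv5 head: one 1x1 convolution per pyramid level."""

    def __init__(self, num_classes: int, in_channels: tuple[int, ...],
                 na: int = 3, input_size: int = 640):
        super().__init__()
        self.nc, self.na = num_classes, na
        self.no = num_classes + 5
        self.m = [nn.Conv2d(c, na * self.no, 1, bias=True) for c in in_channels]
        for conv, stride in zip(self.m, STRIDES):
            b = conv.bias.data.reshape(na, self.no)
            b[:, 4] += math.log(8.0 / (input_size / stride) ** 2)
            b[:, 5:] += math.log(0.6 / (num_classes - 0.99)) if num_classes > 1 else 0.0

    def forward(self, feats):
        out = []
        for conv, x in zip(self.m, feats):
            n, _, h, w = x.shape
            y = conv(x).reshape(n, self.na, self.no, h, w).transpose(0, 1, 3, 4, 2)
            out.append(y)
        return out


class _DecoupledLevel(nn.Module):
    def __init__(self, c_in: int, hidden: int, na: int, nc: int, stride: int,
                 input_size: int):
        super().__init__()
        self.stem = Conv(c_in, hidden, 1)
        self.cls_branch = nn.Sequential(Conv(hidden, hidden, 3), Conv(hidden, hidden, 3))
        self.reg_branch = nn.Sequential(Conv(hidden, hidden, 3), Conv(hidden, hidden, 3))
        self.cls_pred = nn.Conv2d(hidden, na * nc, 1, bias=True)
        self.reg_pred = nn.Conv2d(hidden, na * 4, 1, bias=True)
        self.obj_pred = nn.Conv2d(hidden, na * 1, 1, bias=True)
        self.na, self.nc = na, nc
        self.obj_pred.bias.data += math.log(8.0 / (input_size / stride) ** 2)
        if nc > 1:
            self.cls_pred.bias.data += math.log(0.6 / (nc - 0.99))

    def forward(self, x):
        s = self.stem(x)
        cf = self.cls_branch(s)
        rf = self.reg_branch(s)
        n, _, h, w = x.shape
        cls = self.cls_pred(cf).reshape(n, self.na, self.nc, h, w)
        reg = self.reg_pred(rf).reshape(n, self.na, 4, h, w)
        obj = self.obj_pred(rf).reshape(n, self.na, 1, h, w)
        y = F.concat([reg, obj, cls], axis=2)
        return y.transpose(0, 1, 3, 4, 2)


class DecoupledDetect(nn.Module):
    """Per-level decoupled head (branches share nothing below the stem)."""

    def __init__(self, num_classes: int, in_channels: tuple[int, ...],
                 hidden: int, na: int = 3, input_size: int = 640):
        super().__init__()
        self.nc, self.na = num_classes, na
        self.no = num_classes + 5
        self.m = [
            _DecoupledLevel(c, hidden, na, num_classes, s, input_size)
            for c, s in zip(in_channels, STRIDES)
        ]

    def forward(self, feats):
        return [lvl(x) for lvl, x in zip(self.m, feats)]


class FBStrNet(nn.Module):
    """The assembled detector (backbone + PANet neck + head)."""

    def __init__(self, cfg: ArchitectureConfig | None = None):
        super().__init__()
        cfg = cfg or ArchitectureConfig()
        self.cfg = cfg
        w = lambda c: make_divisible(c * cfg.width_multiple)  # noqa: E731
        d = lambda n: max(round(n * cfg.depth_multiple), 1)  # noqa: E731
        DownConv = GhostConv if cfg.ghost else Conv
        CspBlock = (lambda c1, c2, n: C3Ghost(c1, c2, n)) if cfg.ghost else (
            lambda c1, c2, n: C3(c1, c2, n)
        )

        c64, c128, c256, c512, c1024 = w(64), w(128), w(256), w(512), w(1024)
        # backbone (stem unmodified; substitutions on the four strided
        # convolutions and four C3 blocks that follow it)
        self.backbone = [
            Conv(3, c64, 6, 2, 2),              # 0 stem, stride 2
            DownConv(c64, c128, 3, 2),          # 1 stride 4
            CspBlock(c128, c128, d(3)),         # 2
            DownConv(c128, c256, 3, 2),         # 3 stride 8
            CspBlock(c256, c256, d(6)),         # 4 -> P3 tap
            DownConv(c256, c512, 3, 2),         # 5 stride 16
            CspBlock(c512, c512, d(9)),         # 6 -> P4 tap
            DownConv(c512, c1024, 3, 2),        # 7 stride 32
            CspBlock(c1024, c1024, d(3)),       # 8
            SPPF(c1024, c1024),                 # 9
        ]
        # PANet neck (never ghost-substituted)
        self.neck = [
            Conv(c1024, c512, 1),               # 10
            C3(c1024, c512, d(3), shortcut=False),  # 13 (after up + cat P4)
            Conv(c512, c256, 1),                # 14
            C3(c512, c256, d(3), shortcut=False),   # 17 -> P3 out
            Conv(c256, c256, 3, 2),             # 18
            C3(c512, c512, d(3), shortcut=False),   # 20 -> P4 out
            Conv(c512, c512, 3, 2),             # 21
            C3(c1024, c1024, d(3), shortcut=False),  # 23 -> P5 out
        ]
        taps = (c256, c512, c1024)
        if cfg.decoupled:
            self.head = DecoupledDetect(
                cfg.num_classes, taps, cfg.head_hidden_channels, cfg.na, cfg.input_size
            )
        else:
            self.head = Detect(cfg.num_classes, taps, cfg.na, cfg.input_size)
        self.strides = STRIDES

    def forward(self, x):
        b = self.backbone
        x = b[0](x)
        x = b[2](b[1](x))
        p3 = b[4](b[3](x))
        p4 = b[6](b[5](p3))
        p5 = b[9](b[8](b[7](p4)))

        n10, n13, n14, n17, n18, n20, n21, n23 = self.neck
        t10 = n10(p5)
        y = n13(F.concat([F.upsample_nearest2x(t10), p4], axis=1))
        t14 = n14(y)
        out3 = n17(F.concat([F.upsample_nearest2x(t14), p3], axis=1))
        out4 = n20(F.concat([n18(out3), t14], axis=1))
        out5 = n23(F.concat([n21(out4), t10], axis=1))
        return self.head([out3, out4, out5])


def build_backbone(cfg: ArchitectureConfig) -> list[nn.Module]:
    """The backbone layer list alone (layers 0-9 of the table)."""
    return FBStrNet(cfg).backbone


def build_decoupled_head(cfg: ArchitectureConfig) -> DecoupledDetect:
    """The decoupled head alone, at the configured pyramid widths."""
    w = lambda c: make_divisible(c * cfg.width_multiple)  # noqa: E731
    taps = (w(256), w(512), w(1024))
    return DecoupledDetect(
        cfg.num_classes, taps, cfg.head_hidden_channels, cfg.na, cfg.input_size
    )


def count_parameters(model: FBStrNet) -> ParameterReport:
    """Exact trainable-parameter count, per component and in total."""
    by = {
        "backbone": int(sum(m.num_parameters() for m in model.backbone)),
        "neck": int(sum(m.num_parameters() for m in model.neck)),
        "head": int(model.head.num_parameters()),
    }
    total = sum(by.values())
    return ParameterReport(total=total, by_component=by,
                           millions=ParameterReport.millions_of(total))


# ------------------------------------------------------------- serialization
def save_checkpoint(model: FBStrNet, path) -> None:
    """Weights + architecture config in a single .npz container."""
    d = asdict(model.cfg)
    d["anchors"] = [[list(map(float, a)) for a in lvl] for lvl in model.cfg.anchors]
    cfg_yaml = yaml.safe_dump(d, sort_keys=False)
    state = {k.replace("::", "--"): v for k, v in model.state_dict().items()}
    np.savez(path, __config__=np.array(cfg_yaml), **state)


def load_checkpoint(path) -> FBStrNet:
    with np.load(path, allow_pickle=False) as z:
        d = yaml.safe_load(str(z["__config__"]))
        d["anchors"] = tuple(tuple(tuple(a) for a in lvl) for lvl in d["anchors"])
        cfg = ArchitectureConfig(**d)
        model = FBStrNet(cfg)
        state = {k.replace("--", "::"): z[k] for k in z.files if k != "__config__"}
        model.load_state_dict(state)
    return model
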