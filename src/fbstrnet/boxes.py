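"""Axis-aligned box geometry and IoU-family regression losses.

Boxes live in continuous pixel coordinates, origin at the top-left corner
with y increasing downward; area is (x2-x1)*(y2-y1) with no half-open
pixel semantics. Two interchange forms are used throughout the package:

* corner form ``(x1, y1, x2, y2)`` — detections and ground truth,
* center form ``(cx, cy, w, h)`` — the regression parameterization.

The SIoU loss combines four ingredients: plain IoU, an angle term
``lambda`` that measures how far the line between the two box centers is
from an image axis (0 on axis, 1 at 45 degrees), a distance term
``delta`` on the center offset normalized by the smallest enclosing box
and sharpened by the angle, and a shape term ``omega`` on relative
width/height mismatch raised to the exponent ``theta``:

    L_SIoU = 1 - IoU + (delta + omega) / 2

The core is written against a swappable ``ops`` namespace so the exact
same formulas run on plain numpy arrays (this module's public API) and on
autograd tensors inside the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "BoxXYXY", "BoxCXCYWH", "SIoUTerms",
    "xyxy_to_cxcywh", "cxcywh_to_xyxy",
    "iou", "angle_loss", "distance_loss", "shape_loss", "siou_loss", "ciou_loss",
]

_EPS = 1e-10
DEFAULT_THETA = 4.0


# ----------------------------------------------------------------- box forms
@dataclass(frozen=True)
class BoxXYXY:
    """Corner-form box: (x1, y1) upper-left, (x2, y2) lower-right, pixels."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"box corners out of order: {vals}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def to_cxcywh(self) -> "BoxCXCYWH":
        return BoxCXCYWH(
            (self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0,
            self.x2 - self.x1, self.y2 - self.y1,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class BoxCXCYWH:
    """Center-form box: center (bcx, bcy), width w, height h, pixels."""

    bcx: float
    bcy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w < 0 or self.h < 0:
            raise ValueError(f"box dimensions must be non-negative: w={self.w}, h={self.h}")

    def to_xyxy(self) -> BoxXYXY:
        return BoxXYXY(
            self.bcx - self.w / 2.0, self.bcy - self.h / 2.0,
            self.bcx + self.w / 2.0, self.bcy + self.h / 2.0,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.bcx, self.bcy, self.w, self.h], dtype=np.float64)


def xyxy_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    """Vectorized corner -> center form, boxes shaped (..., 4)."""
    b = np.asarray(boxes, dtype=np.float64)
    out = np.empty_like(b)
    out[..., 0] = (b[..., 0] + b[..., 2]) / 2.0
    out[..., 1] = (b[..., 1] + b[..., 3]) / 2.0
    out[..., 2] = b[..., 2] - b[..., 0]
    out[..., 3] = b[..., 3] - b[..., 1]
    return out


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    """Vectorized center -> corner form, boxes shaped (..., 4)."""
    b = np.asarray(boxes, dtype=np.float64)
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] / 2.0
    out[..., 1] = b[..., 1] - b[..., 3] / 2.0
    out[..., 2] = b[..., 0] + b[..., 2] / 2.0
    out[..., 3] = b[..., 1] + b[..., 3] / 2.0
    return out


# --------------------------------------------------------------------- terms
@dataclass
class SIoUTerms:
    """Every intermediate quantity of the SIoU computation for a box pair.

    Note the deliberate disambiguation of the overloaded symbol "ch":
    ``c_h`` is the enclosing-box height used to normalize the center
    offset, while ``a_h`` is the vertical center offset driving the angle
    term. ``theta`` is the shape-concern exponent.
    """

    iou: float
    lambda_angle: float
    sigma: float
    a_h: float
    c_w: float
    c_h: float
    rho_x: float
    rho_y: float
    gamma: float
    delta: float
    omega_w: float
    omega_h: float
    omega: float
    theta: float
    loss: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _iou_core(g, p, ops):
    inter_w = ops.maximum(ops.minimum(g[..., 2], p[..., 2]) - ops.maximum(g[..., 0], p[..., 0]), 0.0)
    inter_h = ops.maximum(ops.minimum(g[..., 3], p[..., 3]) - ops.maximum(g[..., 1], p[..., 1]), 0.0)
    inter = inter_w * inter_h
    area_g = (g[..., 2] - g[..., 0]) * (g[..., 3] - g[..., 1])
    area_p = (p[..., 2] - p[..., 0]) * (p[..., 3] - p[..., 1])
    union = area_g + area_p - inter
    return inter / ops.maximum(union, _EPS)


def siou_terms_core(gt_xyxy, pred_xyxy, theta, ops) -> dict:
    """SIoU and all intermediates for corner-form inputs shaped (..., 4).

    Generic over the ``ops`` namespace (numpy or autograd functional).
    The degenerate coincident-center case is handled by an epsilon in the
    sigma ratio, which realizes the convention a_h/sigma := 0 (so the
    angle term vanishes, the continuity limit along axis-aligned
    approach).
    """
    g, p = gt_xyxy, pred_xyxy
    iou_v = _iou_core(g, p, ops)

    gcx, gcy = (g[..., 0] + g[..., 2]) * 0.5, (g[..., 1] + g[..., 3]) * 0.5
    pcx, pcy = (p[..., 0] + p[..., 2]) * 0.5, (p[..., 1] + p[..., 3]) * 0.5
    gw, gh = g[..., 2] - g[..., 0], g[..., 3] - g[..., 1]
    pw, ph = p[..., 2] - p[..., 0], p[..., 3] - p[..., 1]

    dx, dy = gcx - pcx, gcy - pcy
    sigma = ops.sqrt(dx * dx + dy * dy)
    a_h = ops.abs(dy)
    ratio = ops.clip(a_h / ops.maximum(sigma, _EPS), 0.0, 1.0)
    lam = 1.0 - 2.0 * ops.sin(ops.arcsin(ratio) - np.pi / 4.0) ** 2

    c_w = ops.maximum(g[..., 2], p[..., 2]) - ops.minimum(g[..., 0], p[..., 0])
    c_h = ops.maximum(g[..., 3], p[..., 3]) - ops.minimum(g[..., 1], p[..., 1])
    rho_x = (dx / ops.maximum(c_w, _EPS)) ** 2
    rho_y = (dy / ops.maximum(c_h, _EPS)) ** 2
    gamma = 2.0 - lam
    delta = (1.0 - ops.exp(-gamma * rho_x)) + (1.0 - ops.exp(-gamma * rho_y))

    omega_w = ops.abs(pw - gw) / ops.maximum(ops.maximum(pw, gw), _EPS)
    omega_h = ops.abs(ph - gh) / ops.maximum(ops.maximum(ph, gh), _EPS)
    omega = (1.0 - ops.exp(-omega_w)) ** theta + (1.0 - ops.exp(-omega_h)) ** theta

    loss = 1.0 - iou_v + (delta + omega) * 0.5
    return {
        "iou": iou_v, "lambda_angle": lam, "sigma": sigma, "a_h": a_h,
        "c_w": c_w, "c_h": c_h, "rho_x": rho_x, "rho_y": rho_y,
        "gamma": gamma, "delta": delta, "omega_w": omega_w, "omega_h": omega_h,
        "omega": omega, "theta": theta, "loss": loss,
    }


def ciou_core(gt_xyxy, pred_xyxy, ops):
    """Complete-IoU loss: 1 - IoU + normalized center distance + aspect term."""
    g, p = gt_xyxy, pred_xyxy
    iou_v = _iou_core(g, p, ops)
    gcx, gcy = (g[..., 0] + g[..., 2]) * 0.5, (g[..., 1] + g[..., 3]) * 0.5
    pcx, pcy = (p[..., 0] + p[..., 2]) * 0.5, (p[..., 1] + p[..., 3]) * 0.5
    gw, gh = g[..., 2] - g[..., 0], g[..., 3] - g[..., 1]
    pw, ph = p[..., 2] - p[..., 0], p[..., 3] - p[..., 1]
    c_w = ops.maximum(g[..., 2], p[..., 2]) - ops.minimum(g[..., 0], p[..., 0])
    c_h = ops.maximum(g[..., 3], p[..., 3]) - ops.minimum(g[..., 1], p[..., 1])
    c2 = c_w * c_w + c_h * c_h + _EPS
    rho2 = (gcx - pcx) ** 2 + (gcy - pcy) ** 2
    v = (4.0 / np.pi**2) * (ops.arctan(gw / (gh + _EPS)) - ops.arctan(pw / (ph + _EPS))) ** 2
    alpha = ops.stop_gradient(v / (1.0 - iou_v + v + _EPS))
    return 1.0 - iou_v + rho2 / c2 + alpha * v


# ------------------------------------------------------- numpy ops namespace
class _NumpyOps:
    exp = staticmethod(np.exp)
    sqrt = staticmethod(np.sqrt)
    sin = staticmethod(np.sin)
    arcsin = staticmethod(np.arcsin)
    arctan = staticmethod(np.arctan)
    abs = staticmethod(np.abs)
    maximum = staticmethod(np.maximum)
    minimum = staticmethod(np.minimum)
    clip = staticmethod(np.clip)

    @staticmethod
    def stop_gradient(x):
        return x


_np_ops = _NumpyOps()


def _check_boxes(*boxes) -> list[np.ndarray]:
    out = []
    for b in boxes:
        arr = np.asarray(
            b.as_array() if isinstance(b, (BoxXYXY, BoxCXCYWH)) else b, dtype=np.float64
        )
        if arr.shape[-1] != 4:
            raise ValueError(f"expected (..., 4) box array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("box coordinates must be finite")
        out.append(arr)
    return out


def _scalarize(x):
    arr = np.asarray(x)
    return float(arr) if arr.ndim == 0 else arr


# ----------------------------------------------------------------- public API
def iou(a, b):
    """Intersection over union of corner-form boxes (broadcasting)."""
    a, b = _check_boxes(a, b)
    return _scalarize(_iou_core(a, b, _np_ops))


def angle_loss(gt, pred):
    """SIoU angle term for center-form boxes; 0 on axis-aligned centers, 1 at 45 deg."""
    gt, pred = _check_boxes(gt, pred)
    g, p = cxcywh_to_xyxy(gt), cxcywh_to_xyxy(pred)
    return _scalarize(siou_terms_core(g, p, DEFAULT_THETA, _np_ops)["lambda_angle"])


def distance_loss(gt, pred, lambda_angle):
    """SIoU distance term for center-form boxes at a given angle term."""
    gt, pred = _check_boxes(gt, pred)
    dx = gt[..., 0] - pred[..., 0]
    dy = gt[..., 1] - pred[..., 1]
    # enclosing box of the two center-form boxes
    g, p = cxcywh_to_xyxy(gt), cxcywh_to_xyxy(pred)
    c_w = np.maximum(g[..., 2], p[..., 2]) - np.minimum(g[..., 0], p[..., 0])
    c_h = np.maximum(g[..., 3], p[..., 3]) - np.minimum(g[..., 1], p[..., 1])
    rho_x = (dx / np.maximum(c_w, _EPS)) ** 2
    rho_y = (dy / np.maximum(c_h, _EPS)) ** 2
    gamma = 2.0 - np.asarray(lambda_angle, dtype=np.float64)
    return _scalarize((1.0 - np.exp(-gamma * rho_x)) + (1.0 - np.exp(-gamma * rho_y)))


def shape_loss(gt, pred, theta: float = DEFAULT_THETA):
    """SIoU shape term for center-form boxes with concern exponent theta."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    gt, pred = _check_boxes(gt, pred)
    omega_w = np.abs(pred[..., 2] - gt[..., 2]) / np.maximum(np.maximum(pred[..., 2], gt[..., 2]), _EPS)
    omega_h = np.abs(pred[..., 3] - gt[..., 3]) / np.maximum(np.maximum(pred[..., 3], gt[..., 3]), _EPS)
    return _scalarize((1.0 - np.exp(-omega_w)) ** theta + (1.0 - np.exp(-omega_h)) ** theta)


def siou_loss(gt, pred, theta: float = DEFAULT_THETA) -> SIoUTerms:
    """Full SIoU decomposition for corner-form boxes.

    Returns an :class:`SIoUTerms` record; fields are floats for single
    boxes and arrays for batched (..., 4) inputs.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    gt, pred = _check_boxes(gt, pred)
    terms = siou_terms_core(gt, pred, theta, _np_ops)
    return SIoUTerms(**{k: _scalarize(v) for k, v in terms.items()})


def ciou_loss(gt, pred):
    """Complete-IoU loss for corner-form boxes (the stock YOLOv5 box loss)."""
    gt, pred = _check_boxes(gt, pred)
    return _scalarize(ciou_core(gt, pred, _np_ops))
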