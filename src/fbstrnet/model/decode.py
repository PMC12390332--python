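"""Decoding raw head outputs into pixel-space detections.

Inverse of the training parameterization: cell offsets are
``2*sigmoid - 0.5`` around the cell, widths/heights are
``(2*sigmoid)^2`` times the anchor, and confidence is the product of
objectness and the best class probability.
"""

from __future__ import annotations

import numpy as np

from ..postfilter import Detection, nms
from .detector import STRIDES, ArchitectureConfig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_predictions(raw: list[np.ndarray], cfg: ArchitectureConfig,
                       conf_threshold: float = 0.25,
                       nms_iou: float = 0.45,
                       max_det: int = 300,
                       apply_nms: bool = True) -> list[list[Detection]]:
    """Raw per-level outputs (N, na, H, W, 5+nc) -> detections per image."""
    anchors_px = cfg.scaled_anchors()
    n_batch = raw[0].shape[0]
    rows = []  # (N_total, 7): img, x1, y1, x2, y2, conf, cls
    for lvl, p in enumerate(raw):
        n, na, h, w, _ = p.shape
        s = _sigmoid(np.asarray(p, dtype=np.float64))
        gy, gx = np.mgrid[0:h, 0:w]
        xy = (s[..., 0:2] * 2.0 - 0.5 + np.stack([gx, gy], axis=-1)) * STRIDES[lvl]
        wh = (s[..., 2:4] * 2.0) ** 2 * anchors_px[lvl][None, :, None, None, :]
        obj = s[..., 4]
        cls_p = s[..., 5:]
        conf = obj[..., None] * cls_p
        best_cls = conf.argmax(axis=-1)
        best_conf = conf.max(axis=-1)
        keep = best_conf > conf_threshold
        if not keep.any():
            continue
        bidx = np.nonzero(keep)[0]
        xy_k, wh_k = xy[keep], wh[keep]
        rows.append(np.column_stack([
            bidx,
            xy_k[:, 0] - wh_k[:, 0] / 2, xy_k[:, 1] - wh_k[:, 1] / 2,
            xy_k[:, 0] + wh_k[:, 0] / 2, xy_k[:, 1] + wh_k[:, 1] / 2,
            best_conf[keep], best_cls[keep],
        ]))
    all_rows = np.concatenate(rows, axis=0) if rows else np.zeros((0, 7))

    out: list[list[Detection]] = []
    size = cfg.input_size
    pre_nms = 4 * max_det  # cap candidates entering NMS
    for i in range(n_batch):
        r = all_rows[all_rows[:, 0] == i]
        if len(r) > pre_nms:
            r = r[np.argsort(-r[:, 5], kind="stable")[:pre_nms]]
        dets = [
            Detection(
                float(np.clip(x1, 0, size)), float(np.clip(y1, 0, size)),
                float(np.clip(max(x2, x1), 0, size)), float(np.clip(max(y2, y1), 0, size)),
                float(np.clip(c, 0.0, 1.0)), int(k),
            )
            for _, x1, y1, x2, y2, c, k in r
        ]
        if apply_nms:
            dets = nms(dets, nms_iou)[:max_det]
        else:
            dets = sorted(dets, key=lambda d: -d.conf)[:max_det]
        out.append(dets)
    return out
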