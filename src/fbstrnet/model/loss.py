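"""Composite detection training objective.

Three weighted terms, per the YOLOv5 recipe: a box-regression term using
the configured IoU-family loss (CIoU or SIoU) on assigned anchors, an
objectness term (binary cross-entropy against the achieved IoU, with
per-level balance weights), and a per-class binary cross-entropy term.
Only the box term differs between the CIoU baseline and the SIoU model.
"""

from __future__ import annotations

import numpy as np

from ..boxes import ciou_core, siou_terms_core
from ..nn import Tensor
from ..nn import functional as F
from .assign import build_targets
from .detector import ArchitectureConfig, STRIDES

_BALANCE = (4.0, 1.0, 0.4)  # objectness weight per pyramid level


def _corner_form(cx, cy, w, h):
    """Stack center-form components into an (M, 4) corner-form tensor."""
    half_w, half_h = w * 0.5, h * 0.5
    cols = [cx - half_w, cy - half_h, cx + half_w, cy + half_h]
    return F.concat([c.reshape(-1, 1) for c in cols], axis=1)


class DetectionLoss:
    """Callable computing the total training loss for one batch."""

    def __init__(self, cfg: ArchitectureConfig, anchor_t: float = 5.0,
                 box_gain: float = 0.05, obj_gain: float = 1.0,
                 cls_gain: float = 0.5):
        self.cfg = cfg
        self.anchor_t = anchor_t
        self.gains = (box_gain, obj_gain, cls_gain)
        anchors_px = cfg.scaled_anchors()  # (3, 3, 2) at the input size
        self.anchors_grid = [anchors_px[i] / STRIDES[i] for i in range(3)]

    def __call__(self, preds: list[Tensor], targets: np.ndarray
                 ) -> tuple[Tensor, dict[str, float]]:
        """``preds``: per-level (N, na, H, W, 5+nc) raw head outputs.

        ``targets``: (nt, 6) rows (image_index, class, cx, cy, w, h),
        normalized. Returns (total loss tensor, float components).
        """
        nc = self.cfg.num_classes
        grid_shapes = [(p.shape[2], p.shape[3]) for p in preds]
        assigned = build_targets(targets, grid_shapes, self.anchors_grid, self.anchor_t)

        lbox = Tensor(0.0)
        lobj = Tensor(0.0)
        lcls = Tensor(0.0)
        for i, (pi, lt) in enumerate(zip(preds, assigned)):
            tobj = np.zeros(pi.shape[:4], dtype=np.float32)
            if lt.n:
                ps = pi[(lt.b, lt.a, lt.gj, lt.gi)]  # (M, 5+nc)
                pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
                pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * lt.anchors
                pbox = _corner_form(pxy[:, 0], pxy[:, 1], pwh[:, 0], pwh[:, 1])
                tb = lt.tbox
                gbox = np.stack([
                    tb[:, 0] - tb[:, 2] / 2, tb[:, 1] - tb[:, 3] / 2,
                    tb[:, 0] + tb[:, 2] / 2, tb[:, 1] + tb[:, 3] / 2,
                ], axis=1)
                if self.cfg.loss_name == "SIoU":
                    terms = siou_terms_core(gbox, pbox, self.cfg.theta, F)
                    per_pair = terms["loss"]
                    iou_v = terms["iou"]
                else:
                    per_pair = ciou_core(gbox, pbox, F)
                    # recover plain IoU for the objectness target
                    from ..boxes import _iou_core

                    iou_v = _iou_core(gbox, pbox, F)
                lbox = lbox + per_pair.mean()
                iou_np = np.clip(iou_v.detach().data, 0.0, 1.0)
                tobj[lt.b, lt.a, lt.gj, lt.gi] = iou_np.astype(np.float32)
                if nc > 1:
                    t = np.zeros((lt.n, nc), dtype=np.float32)
                    t[np.arange(lt.n), lt.tcls] = 1.0
                    lcls = lcls + F.bce_with_logits(ps[:, 5:], t)
            lobj = lobj + F.bce_with_logits(pi[..., 4], tobj) * _BALANCE[i]

        bg, og, cg = self.gains
        total = lbox * bg + lobj * og + lcls * cg
        return total, {
            "box": float(lbox.data) * bg,
            "obj": float(lobj.data) * og,
            "cls": float(lcls.data) * cg,
            "total": float(total.data),
        }
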