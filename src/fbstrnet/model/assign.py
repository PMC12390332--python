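"""Anchor-based training-target assignment (YOLOv5 scheme).

A ground-truth box is assigned, on every pyramid level, to each anchor
whose width/height ratio to the box is within the anchor threshold
(max(r, 1/r) < anchor_t), at its own grid cell and up to two neighboring
cells (the lateral-expansion trick that triples positive samples). Box
regression targets are expressed as (offset into cell, width/height in
grid units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LevelTargets:
    """Assigned targets for one pyramid level."""

    b: np.ndarray    # image index in batch
    a: np.ndarray    # anchor index
    gj: np.ndarray   # grid row
    gi: np.ndarray   # grid column
    tbox: np.ndarray  # (M, 4): cell offset x, y and grid-unit w, h
    tcls: np.ndarray  # (M,)
    anchors: np.ndarray  # (M, 2) matched anchor shapes, grid units

    @property
    def n(self) -> int:
        return len(self.b)


_OFFSETS = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], dtype=np.float64)
_BIAS = 0.5  # neighbor-cell expansion radius


def build_targets(targets: np.ndarray, grid_shapes: list[tuple[int, int]],
                  anchors_grid: list[np.ndarray], anchor_t: float = 5.0
                  ) -> list[LevelTargets]:
    """Assign normalized labels to anchors on every level.

    ``targets``: (nt, 6) rows of (image_index, class, cx, cy, w, h), all
    box fields normalized to [0, 1]. ``anchors_grid[i]``: (na, 2) anchor
    shapes in grid units of level i.
    """
    targets = np.asarray(targets, dtype=np.float64).reshape(-1, 6)
    out: list[LevelTargets] = []
    nt = len(targets)
    for (h, w), anchors in zip(grid_shapes, anchors_grid):
        na = len(anchors)
        gain = np.array([1.0, 1.0, w, h, w, h])
        t = targets * gain
        if nt:
            r = t[None, :, 4:6] / anchors[:, None, :]  # (na, nt, 2)
            keep = np.maximum(r, 1.0 / r).max(axis=2) < anchor_t
            ai = np.repeat(np.arange(na)[:, None], nt, axis=1)
            t_rep = np.broadcast_to(t, (na, nt, 6))[keep]
            a_idx = ai[keep]
            if len(t_rep):
                gxy = t_rep[:, 2:4]
                gxi = gain[[2, 3]] - gxy
                jk = (gxy % 1.0 < _BIAS) & (gxy > 1.0)
                lm = (gxi % 1.0 < _BIAS) & (gxi > 1.0)
                sel = np.stack([
                    np.ones(len(t_rep), dtype=bool),
                    jk[:, 0], jk[:, 1], lm[:, 0], lm[:, 1],
                ])
                t_all = np.repeat(t_rep[None], 5, axis=0)[sel]
                a_all = np.repeat(a_idx[None], 5, axis=0)[sel]
                offs = (np.zeros((5, len(t_rep), 2)) + _OFFSETS[:, None] * _BIAS)[sel]
            else:
                t_all = np.zeros((0, 6))
                a_all = np.zeros(0, dtype=int)
                offs = np.zeros((0, 2))
        else:
            t_all = np.zeros((0, 6))
            a_all = np.zeros(0, dtype=int)
            offs = np.zeros((0, 2))

        gxy = t_all[:, 2:4]
        gij = (gxy - offs).astype(int)
        gi = np.clip(gij[:, 0], 0, w - 1)
        gj = np.clip(gij[:, 1], 0, h - 1)
        out.append(LevelTargets(
            b=t_all[:, 0].astype(int),
            a=a_all,
            gj=gj,
            gi=gi,
            tbox=np.concatenate([gxy - np.stack([gi, gj], axis=1), t_all[:, 4:6]], axis=1),
            tcls=t_all[:, 1].astype(int),
            anchors=np.asarray(anchors)[a_all] if len(a_all) else np.zeros((0, 2)),
        ))
    return out
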