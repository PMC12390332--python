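"""Detection evaluation: precision, recall, average precision and mAP.

Definitions follow the standard single-class bookkeeping: a detection is
a true positive (TP) at IoU threshold ``t`` if its best-overlapping,
not-yet-matched ground-truth box of the same class has IoU >= t, and a
false positive (FP) otherwise; ground truths left unmatched are false
negatives (FN). Matching is greedy in descending confidence. AP is the
area under the precision envelope over recall (all-point interpolation,
the YOLOv5 convention; the 101-point COCO variant is available behind a
flag), and mAP averages AP over classes that have ground truth — at IoU
0.5 for mAP@0.5 and over the ten thresholds 0.50:0.05:0.95 for
mAP@0.5:0.95.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou
from .postfilter import CLASS_INDEX, CLASS_NAMES, Detection

__all__ = [
    "MatchResult", "PRCurve", "EvalReport", "IOU_GRID",
    "match_detections", "precision_recall", "average_precision",
    "mean_ap", "evaluate",
]

log = logging.getLogger(__name__)

IOU_GRID = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))  # 0.50 ... 0.95


@dataclass
class MatchResult:
    """TP/FP flags per detection (confidence-ordered) plus FN count."""

    tp_flags: np.ndarray  # bool, aligned with conf-descending detections
    conf: np.ndarray
    n_gt: int

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


@dataclass
class PRCurve:
    """Cumulative precision/recall over the confidence ranking, plus AP."""

    precision: np.ndarray
    recall: np.ndarray
    ap: float


def match_detections(dets: list[Detection], gts: list[Detection],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy confidence-descending matching within one image and class.

    Each ground truth can absorb at most one detection; a detection
    matches the unmatched ground truth with the highest IoU, provided
    that IoU reaches the threshold.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].conf, i))
    flags = np.zeros(len(dets), dtype=bool)
    conf = np.array([dets[i].conf for i in order], dtype=np.float64)
    taken = np.zeros(len(gts), dtype=bool)
    for rank, i in enumerate(order):
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(dets[i].box, g.box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            flags[rank] = True
    return MatchResult(tp_flags=flags, conf=conf, n_gt=len(gts))


def precision_recall(match: MatchResult) -> tuple[float, float]:
    """Overall precision and recall of a match result (0 when undefined)."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def average_precision(tp_flags: np.ndarray, n_gt: int,
                      method: str = "continuous") -> PRCurve:
    """AP from confidence-ranked TP/FP flags.

    ``method='continuous'`` integrates the precision envelope over every
    recall change (all-point interpolation); ``method='interp101'`` uses
    the 101-point COCO grid.
    """
    flags = np.asarray(tp_flags, dtype=bool)
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    if n_gt == 0 or flags.size == 0:
        return PRCurve(np.zeros(0), np.zeros(0), 0.0)
    tpc = np.cumsum(flags)
    fpc = np.cumsum(~flags)
    recall = tpc / n_gt
    precision = tpc / (tpc + fpc)

    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.flip(np.maximum.accumulate(np.flip(mpre)))  # precision envelope
    if method == "continuous":
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    elif method == "interp101":
        grid = np.linspace(0.0, 1.0, 101)
        ap = float(np.trapezoid(np.interp(grid, mrec, mpre), grid))
    else:
        raise ValueError(f"unknown AP method {method!r}")
    return PRCurve(precision=precision, recall=recall, ap=ap)


def mean_ap(per_class_ap: dict[int, float]) -> float:
    """Unweighted mean over the evaluated classes."""
    if not per_class_ap:
        return 0.0
    return float(np.mean(list(per_class_ap.values())))


@dataclass
class EvalReport:
    """Full evaluation over a dataset of per-image detections and labels."""

    map50: float
    map50_95: float
    per_class_ap50: dict[str, float]
    precision: float
    recall: float
    n_images: int
    curves: dict[str, PRCurve] = field(default_factory=dict)
    skipped_classes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mAP@0.5": self.map50,
                "mAP@0.5:0.95": self.map50_95,
                "precision": self.precision,
                "recall": self.recall,
                "per_class_AP@0.5": self.per_class_ap50,
                "n_images": self.n_images,
                "skipped_classes": self.skipped_classes,
            },
            indent=2,
        )

    def to_table(self, params_m: float | None = None) -> str:
        cols = f"{'Precision':>10} {'Recall':>8} {'mAP@0.5':>9} {'mAP@0.5:0.95':>13}"
        row = f"{self.precision:>10.3f} {self.recall:>8.3f} {self.map50:>9.3f} {self.map50_95:>13.3f}"
        if params_m is not None:
            cols += f" {'Params (M)':>11}"
            row += f" {params_m:>11.1f}"
        lines = [cols, row, "", "per-class AP@0.5:"]
        lines += [f"  {name:>4}: {ap:.3f}" for name, ap in self.per_class_ap50.items()]
        return "\n".join(lines)

    def curves_to_csv(self, path) -> None:
        """P-R curve per class as CSV (class, precision, recall rows)."""
        with open(path, "w") as fh:
            fh.write("class,recall,precision\n")
            for name, curve in self.curves.items():
                for r, p in zip(curve.recall, curve.precision):
                    fh.write(f"{name},{r:.6f},{p:.6f}\n")


def _class_flags(dets_by_image: dict, gts_by_image: dict, cls: int,
                 iou_threshold: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled confidence-ranked TP flags for one class across all images."""
    conf_all, flag_all, n_gt = [], [], 0
    for img_id, gts in gts_by_image.items():
        gts_c = [g for g in gts if g.cls == cls]
        dets_c = [d for d in dets_by_image.get(img_id, []) if d.cls == cls]
        n_gt += len(gts_c)
        m = match_detections(dets_c, gts_c, iou_threshold)
        conf_all.append(m.conf)
        flag_all.append(m.tp_flags)
    # also count detections on images that have labels files but no GT of cls
    for img_id, dets in dets_by_image.items():
        if img_id not in gts_by_image:
            dets_c = [d for d in dets if d.cls == cls]
            conf_all.append(np.array([d.conf for d in dets_c]))
            flag_all.append(np.zeros(len(dets_c), dtype=bool))
    conf = np.concatenate(conf_all) if conf_all else np.zeros(0)
    flags = np.concatenate(flag_all) if flag_all else np.zeros(0, dtype=bool)
    order = np.argsort(-conf, kind="stable")
    return flags[order], conf[order], n_gt


def evaluate(dets_by_image: dict[str, list[Detection]],
             gts_by_image: dict[str, list[Detection]],
             iou_grid: tuple[float, ...] = IOU_GRID,
             ap_method: str = "continuous") -> EvalReport:
    """Dataset-level evaluation.

    Classes absent from the ground truth are excluded from the class
    means (and reported in ``skipped_classes``). The headline precision
    and recall are taken at the operating point of maximal F1 on the
    pooled IoU-0.5 curve, averaged over classes.
    """
    per_class_ap50: dict[str, float] = {}
    ap_grid: dict[int, list[float]] = {}
    curves: dict[str, PRCurve] = {}
    skipped: list[str] = []
    precisions, recalls = [], []

    for cls, name in enumerate(CLASS_NAMES):
        flags50, _conf, n_gt = _class_flags(dets_by_image, gts_by_image, cls, 0.5)
        if n_gt == 0:
            skipped.append(name)
            continue
        curve = average_precision(flags50, n_gt, ap_method)
        per_class_ap50[name] = curve.ap
        curves[name] = curve
        aps = [curve.ap]
        for t in iou_grid:
            if abs(t - 0.5) < 1e-9:
                continue
            f, _, n = _class_flags(dets_by_image, gts_by_image, cls, float(t))
            aps.append(average_precision(f, n, ap_method).ap)
        ap_grid[cls] = aps
        if curve.precision.size:
            f1 = 2 * curve.precision * curve.recall / np.maximum(
                curve.precision + curve.recall, 1e-12
            )
            k = int(np.argmax(f1))
            precisions.append(float(curve.precision[k]))
            recalls.append(float(curve.recall[k]))
        else:
            precisions.append(0.0)
            recalls.append(0.0)

    if skipped:
        log.info("classes without ground truth skipped from mAP: %s", skipped)

    map50 = mean_ap({CLASS_INDEX[n]: ap for n, ap in per_class_ap50.items()})
    map50_95 = (
        float(np.mean([np.mean(v) for v in ap_grid.values()])) if ap_grid else 0.0
    )
    return EvalReport(
        map50=map50,
        map50_95=map50_95,
        per_class_ap50=per_class_ap50,
        precision=float(np.mean(precisions)) if precisions else 0.0,
        recall=float(np.mean(recalls)) if recalls else 0.0,
        n_images=len(gts_by_image),
        curves=curves,
        skipped_classes=skipped,
    )

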