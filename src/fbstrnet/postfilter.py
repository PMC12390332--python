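"""Detection post-processing: confidence gating, class-wise NMS, and the
clinically informed plane-aware filter.

First-trimester fetal-brain screening uses four standard planes, each of
which can only contain a fixed set of anatomical structures (the
``P_OBJS`` prior): e.g. the trans-lateral-ventricular axial plane shows
the cranial bone, the brain midline and the two (paired) choroid
plexuses. The filter drops detections whose class cannot occur in the
imaged plane, keeps the single most confident detection per class above
a strict confidence gate (two for the paired choroid plexus), and
returns the survivors sorted by class index. This removes duplicate and
anatomically impossible detections that survive plain NMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import iou

__all__ = [
    "CLASS_NAMES", "CLASS_INDEX", "PLANES", "P_OBJS", "Detection",
    "nms", "filter_detections", "infer_plane",
]

# Canonical class table (index order fixed across the whole package).
CLASS_NAMES = ("CB", "BM", "CP", "CM", "B", "FV", "AS", "T&P", "NB", "M", "TV", "HP")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

# Fixed plane order (used for tie-breaking in plane inference).
PLANES = ("TLVAP", "TTAP", "TPFAP", "MSP")

# Plane -> expected structure classes. The choroid plexus (CP) is paired,
# so TLVAP images contain two CP instances of the single CP class.
P_OBJS: dict[str, frozenset[str]] = {
    "TLVAP": frozenset({"CB", "BM", "CP"}),
    "TTAP": frozenset({"CB", "BM", "AS", "T&P"}),
    "TPFAP": frozenset({"CB", "CM", "B", "FV"}),
    "MSP": frozenset({"CB", "CM", "B", "FV", "NB", "M", "TV", "HP"}),
}

DEFAULT_CONF_THRESHOLD = 0.5
DEFAULT_NMS_IOU = 0.45


@dataclass(frozen=True)
class Detection:
    """One detection record: corner-form box, confidence, class index."""

    x1: float
    y1: float
    x2: float
    y2: float
    conf: float
    cls: int

    def __post_init__(self):
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.conf}")
        if not (0 <= self.cls < len(CLASS_NAMES)):
            raise ValueError(f"class index {self.cls} outside canonical table")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError("box corners out of order")

    @property
    def box(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.cls]


def nms(dets: list[Detection], iou_threshold: float = DEFAULT_NMS_IOU) -> list[Detection]:
    """Class-wise greedy non-maximum suppression.

    Detections are swept in descending confidence; a detection is
    suppressed if it overlaps an already-kept detection of the same
    class with IoU strictly above the threshold. Output is ordered by
    descending confidence.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in [0, 1], got {iou_threshold}")
    if not dets:
        return []
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].conf, i))
    boxes = np.array([dets[i].box for i in order])
    cls = np.array([dets[i].cls for i in order])
    alive = np.ones(len(order), dtype=bool)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept_idx.append(order[i])
        rest = alive.copy()
        rest[: i + 1] = False
        rest &= cls == cls[i]
        if rest.any():
            overlaps = iou(boxes[i], boxes[rest])
            sup = np.asarray(overlaps) > iou_threshold
            alive[np.nonzero(rest)[0][sup]] = False
    return [dets[i] for i in kept_idx]


def _sorted_output(records: list[Detection]) -> list[Detection]:
    # ascending class index; within a class, descending confidence
    return sorted(records, key=lambda d: (d.cls, -d.conf))


def filter_detections(
    dets: list[Detection],
    plane: str,
    prior: dict[str, frozenset[str]] | None = None,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> list[Detection]:
    """Plane-aware filtering and sorting of detections.

    Steps, in order:

    1. drop detections whose class is not expected in ``plane``;
    2. among survivors with ``conf > conf_threshold`` (strict), keep the
       single most confident detection per class;
    3. for the paired choroid plexus (CP), keep the top two by
       confidence instead of one;
    4. concatenate, remove exact duplicates (all six fields), and sort
       ascending by class index.

    The output is always a subset of the input records.
    """
    prior = P_OBJS if prior is None else prior
    if plane not in prior:
        raise ValueError(f"unknown plane {plane!r}; valid planes: {sorted(prior)}")
    expected = prior[plane]

    # Step 1: anatomical-prior gate
    filtered = [d for d in dets if d.class_name in expected]

    # Step 2: strict confidence gate, best per class
    best: dict[int, Detection] = {}
    for d in filtered:
        if d.conf > conf_threshold:
            if d.cls not in best or d.conf > best[d.cls].conf:
                best[d.cls] = d

    # Step 3: paired CP keeps the top two
    cp = CLASS_INDEX["CP"]
    top_cp: list[Detection] = []
    if "CP" in expected:
        cp_dets = sorted(
            (d for d in filtered if d.cls == cp and d.conf > conf_threshold),
            key=lambda d: -d.conf,
        )
        top_cp = cp_dets[:2]

    # Step 4: concatenate, deduplicate on all fields, sort by class
    merged: list[Detection] = []
    seen: set[tuple] = set()
    for d in list(best.values()) + top_cp:
        key = (d.x1, d.y1, d.x2, d.y2, d.conf, d.cls)
        if key not in seen:
            seen.add(key)
            merged.append(d)
    return _sorted_output(merged)


def infer_plane(dets: list[Detection], prior: dict[str, frozenset[str]] | None = None) -> str:
    """Guess the standard plane from the detected class set.

    Scores each plane by (number of detected classes it expects) minus
    (number it does not); ties break toward the smaller expected set,
    then the fixed plane order. This is a pragmatic stopgap for callers
    that do not know the imaged plane.
    """
    if not dets:
        raise ValueError("cannot infer a plane from zero detections")
    prior = P_OBJS if prior is None else prior
    present = {d.class_name for d in dets}
    plane_order = [p for p in PLANES if p in prior] + [p for p in prior if p not in PLANES]
    best_plane, best_key = None, None
    for rank, plane in enumerate(plane_order):
        expected = prior[plane]
        score = len(present & expected) - len(present - expected)
        key = (-score, len(expected), rank)
        if best_key is None or key < best_key:
            best_plane, best_key = plane, key
    return best_plane
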