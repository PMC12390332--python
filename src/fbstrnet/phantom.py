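"""Synthetic fetal-brain ultrasound phantoms.

Each phantom is a schematic rendering of one of the four first-trimester
standard planes on a dark fan-shaped (sector-scan) field: a bright
elliptical skull ring (CB), a midline echo (BM), paired bright choroid
plexuses (CP), hypoechoic fluid spaces (FV, TV, CM, AS), the thalamus
and cerebral peduncles (T&P), the brainstem (B), and short bright bone
echoes (NB, M, HP) — whichever set the imaged plane is expected to
contain. Multiplicative smoothed Rayleigh speckle and a light Gaussian
blur emulate the granular low-SNR texture of ultrasound.

Layouts are schematic, not anatomically calibrated: their purpose is
class-consistent, learnable structure at desk scale, with ground-truth
boxes that are exact by construction. Every image is a pure function of
its seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage.draw import disk, ellipse, line

from .postfilter import CLASS_INDEX, CLASS_NAMES, P_OBJS, PLANES, Detection

__all__ = [
    "PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset",
    "read_yolo_labels", "write_yolo_labels", "load_manifest",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image.

    Jitter fields are relative standard deviations applied to structure
    placement; ``speckle_strength`` in [0, 1] blends the multiplicative
    speckle field into the clean rendering.
    """

    plane: str
    image_size: int = 640
    seed: int = 0
    background: float = 0.20
    skull_intensity: float = 0.88
    speckle_strength: float = 0.5
    speckle_smooth_sigma: float = 1.2
    blur_sigma: float = 0.8
    jitter: float = 0.04
    fan_apex_y: float = -0.25
    fan_half_angle_deg: float = 38.0
    contrast_margin: float = 0.05  # guaranteed |structure - background| contrast

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; valid: {PLANES}")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")


@dataclass
class PhantomSample:
    """Rendered image plus exact ground truth (conf = 1 per label)."""

    image: np.ndarray  # uint8 grayscale (S, S)
    labels: list[Detection]
    plane: str
    seed: int


# ------------------------------------------------------------------ geometry
def _fan_mask(size: int, apex_y: float, half_angle_deg: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    ax, ay = size / 2.0, apex_y * size
    dy, dx = yy - ay, xx - ax
    ang = np.abs(np.arctan2(dx, dy))  # 0 along the beam axis (downwards)
    r = np.hypot(dx, dy)
    return (ang < np.deg2rad(half_angle_deg)) & (r < 1.35 * size)


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    # +1 on the far corner: the box spans the covered pixel area
    return float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)


class _Canvas:
    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        s = spec.image_size
        self.size = s
        self.rng = rng
        self.spec = spec
        self.jit = spec.jitter
        self.fan = _fan_mask(s, spec.fan_apex_y, spec.fan_half_angle_deg)
        self.img = np.full((s, s), 0.03, dtype=np.float64)
        self.img[self.fan] = spec.background
        self.labels: list[Detection] = []

    def j(self, v: float, scale: float = 1.0) -> float:
        return v + self.rng.normal(0.0, self.jit * scale)

    def _paint(self, mask: np.ndarray, intensity: float, cls_name: str | None):
        mask = mask & self.fan
        if cls_name is not None and not mask.any():
            raise ValueError(f"structure {cls_name} fell outside the imaging fan")
        self.img[mask] = intensity
        if cls_name is not None:
            x1, y1, x2, y2 = _tight_box(mask)
            self.labels.append(Detection(x1, y1, x2, y2, 1.0, CLASS_INDEX[cls_name]))

    def ellipse_ring(self, cy, cx, ry, rx, thickness, rot, intensity, cls_name):
        s = self.size
        outer = np.zeros((s, s), dtype=bool)
        rr, cc = ellipse(cy * s, cx * s, ry * s, rx * s, shape=(s, s), rotation=rot)
        outer[rr, cc] = True
        inner = np.zeros((s, s), dtype=bool)
        rr, cc = ellipse(
            cy * s, cx * s, (ry - thickness) * s, (rx - thickness) * s,
            shape=(s, s), rotation=rot,
        )
        inner[rr, cc] = True
        self._paint(outer & ~inner, intensity, cls_name)
        return outer

    def filled_ellipse(self, cy, cx, ry, rx, rot, intensity, cls_name,
                       combine_with=None):
        s = self.size
        m = np.zeros((s, s), dtype=bool)
        rr, cc = ellipse(cy * s, cx * s, ry * s, rx * s, shape=(s, s), rotation=rot)
        m[rr, cc] = True
        if combine_with is not None:
            m |= combine_with
        self._paint(m, intensity, cls_name)
        return m

    def ellipse_mask(self, cy, cx, ry, rx, rot=0.0) -> np.ndarray:
        s = self.size
        m = np.zeros((s, s), dtype=bool)
        rr, cc = ellipse(cy * s, cx * s, ry * s, rx * s, shape=(s, s), rotation=rot)
        m[rr, cc] = True
        return m

    def thick_line(self, y0, x0, y1, x1, width, intensity, cls_name):
        s = self.size
        m = np.zeros((s, s), dtype=bool)
        rr, cc = line(int(y0 * s), int(x0 * s), int(y1 * s), int(x1 * s))
        m[np.clip(rr, 0, s - 1), np.clip(cc, 0, s - 1)] = True
        it = max(int(round(width * s)), 1)
        m = ndimage.binary_dilation(m, iterations=it)
        self._paint(m, intensity, cls_name)
        return m

    def spot(self, cy, cx, r, intensity, cls_name):
        s = self.size
        m = np.zeros((s, s), dtype=bool)
        rr, cc = disk((cy * s, cx * s), max(r * s, 2.0), shape=(s, s))
        m[rr, cc] = True
        self._paint(m, intensity, cls_name)
        return m


# ------------------------------------------------------------------- layouts
def _render_axial(cv: _Canvas, plane: str):
    """TLVAP / TTAP / TPFAP: axial view, bright skull ring + midline anatomy."""
    rot = cv.rng.normal(0.0, 0.12)
    cy, cx = cv.j(0.55), cv.j(0.50)
    ry, rx = cv.j(0.27, 0.5), cv.j(0.33, 0.5)
    cv.ellipse_ring(cy, cx, ry, rx, 0.030, rot, cv.spec.skull_intensity, "CB")

    if plane in ("TLVAP", "TTAP"):
        cv.thick_line(cy - ry * 0.78, cx, cy + ry * 0.78, cx, 0.006, 0.80, "BM")
    if plane == "TLVAP":
        # paired choroid plexuses, one per hemisphere
        for side in (-1.0, +1.0):
            cv.filled_ellipse(
                cv.j(cy - 0.035, 0.4), cv.j(cx + side * 0.135, 0.4),
                cv.j(0.115, 0.3), cv.j(0.062, 0.3), side * 0.25, 0.74, "CP",
            )
    elif plane == "TTAP":
        # butterfly of thalamus + cerebral peduncles (one structure), then
        # the aqueduct as a small fluid spot behind it
        left = cv.ellipse_mask(cy + 0.01, cx - 0.075, 0.065, 0.055, 0.5)
        cv.filled_ellipse(cy + 0.01, cx + 0.075, 0.065, 0.055, -0.5, 0.62, "T&P",
                          combine_with=left)
        cv.spot(cv.j(cy + 0.135, 0.3), cv.j(cx, 0.3), 0.024, 0.08, "AS")
    elif plane == "TPFAP":
        cv.filled_ellipse(cv.j(cy - 0.06, 0.3), cv.j(cx, 0.3), 0.075, 0.105,
                          0.0, 0.58, "B")
        cv.filled_ellipse(cv.j(cy + 0.065, 0.3), cv.j(cx, 0.3), 0.032, 0.050,
                          0.0, 0.07, "FV")
        cv.filled_ellipse(cv.j(cy + 0.165, 0.3), cv.j(cx, 0.3), 0.042, 0.125,
                          0.0, 0.10, "CM")


def _render_msp(cv: _Canvas):
    """Mid-sagittal plane: profile view with facial bones and fossa anatomy."""
    rot = cv.rng.normal(0.0, 0.10)
    cy, cx = cv.j(0.50), cv.j(0.54)
    ry, rx = cv.j(0.26, 0.5), cv.j(0.30, 0.5)
    cv.ellipse_ring(cy, cx, ry, rx, 0.028, rot, cv.spec.skull_intensity, "CB")
    cv.filled_ellipse(cv.j(cy + 0.07, 0.3), cv.j(cx + 0.02, 0.3), 0.055, 0.085,
                      0.35, 0.60, "B")
    cv.filled_ellipse(cv.j(cy + 0.035, 0.3), cv.j(cx - 0.065, 0.3), 0.030, 0.022,
                      0.0, 0.08, "TV")
    cv.filled_ellipse(cv.j(cy + 0.125, 0.3), cv.j(cx + 0.075, 0.3), 0.028, 0.040,
                      0.3, 0.07, "FV")
    cv.filled_ellipse(cv.j(cy + 0.185, 0.3), cv.j(cx + 0.125, 0.3), 0.035, 0.052,
                      0.2, 0.11, "CM")
    # facial bone echoes anterior-inferior to the skull
    nbx, nby = cv.j(cx - rx - 0.015, 0.3), cv.j(cy + 0.16, 0.3)
    cv.thick_line(nby, nbx, nby + 0.022, nbx + 0.065, 0.008, 0.86, "NB")
    cv.thick_line(nby + 0.075, nbx + 0.01, nby + 0.085, nbx + 0.075, 0.008, 0.82, "HP")
    cv.thick_line(nby + 0.150, nbx + 0.02, nby + 0.175, nbx + 0.070, 0.009, 0.84, "M")


def _apply_speckle(img: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    noise = rng.rayleigh(scale=1.0, size=img.shape)
    noise = ndimage.gaussian_filter(noise, spec.speckle_smooth_sigma)
    noise /= noise.mean()
    a = spec.speckle_strength
    out = img * ((1.0 - a) + a * noise)
    out = ndimage.gaussian_filter(out, spec.blur_sigma)
    return np.clip(out, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; deterministic for a fixed spec (bit-identical)."""
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    cv = _Canvas(spec, rng)
    if spec.plane == "MSP":
        _render_msp(cv)
    else:
        _render_axial(cv, spec.plane)

    expected = sorted(P_OBJS[spec.plane])
    got = sorted({d.class_name for d in cv.labels})
    assert got == expected, f"composition mismatch for {spec.plane}: {got}"

    img = _apply_speckle(cv.img, spec, rng)
    img8 = (img * 255.0).round().astype(np.uint8)
    return PhantomSample(image=img8, labels=cv.labels, plane=spec.plane, seed=spec.seed)


# ---------------------------------------------------------------- label I/O
def write_yolo_labels(path, labels: list[Detection], image_size: int,
                      with_conf: bool = False) -> None:
    """YOLO txt: one `cls cx cy w h [conf]` line per box, normalized."""
    s = float(image_size)
    lines = []
    for d in labels:
        cx, cy = (d.x1 + d.x2) / 2 / s, (d.y1 + d.y2) / 2 / s
        w, h = (d.x2 - d.x1) / s, (d.y2 - d.y1) / s
        row = f"{d.cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if with_conf:
            row += f" {d.conf:.6f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, image_size: int) -> list[Detection]:
    out = []
    for row in Path(path).read_text().splitlines():
        parts = row.split()
        if not parts:
            continue
        cls = int(parts[0])
        cx, cy, w, h = (float(v) * image_size for v in parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        out.append(Detection(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, conf, cls))
    return out


def _derive_seed(seed: int, plane: str, index: int) -> int:
    """Stable cross-platform per-image seed from (seed, plane, index)."""
    h = hashlib.sha256(f"{seed}:{plane}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def generate_dataset(n_per_plane: int, seed: int, out_dir,
                     image_size: int = 640, val_fraction: float = 0.2,
                     spec_overrides: dict | None = None) -> Path:
    """Write a YOLO-layout phantom dataset and return the manifest path.

    Layout: ``images/{train,val}/*.png``, ``labels/{train,val}/*.txt`` and
    a ``data.yaml`` manifest with class names in canonical order and a
    per-image plane map. Per-image seeds are a pure function of
    (seed, plane, index), so regeneration is reproducible file-for-file.
    """
    if n_per_plane < 1:
        raise ValueError("n_per_plane must be >= 1")
    out = Path(out_dir)
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    n_val = int(round(n_per_plane * val_fraction))
    planes_map: dict[str, str] = {}
    splits: dict[str, list[str]] = {"train": [], "val": []}
    overrides = spec_overrides or {}
    for plane in PLANES:
        for idx in range(n_per_plane):
            split = "val" if idx < n_val else "train"
            stem = f"{plane.lower()}_{idx:04d}"
            spec = PhantomSpec(
                plane=plane, image_size=image_size,
                seed=_derive_seed(seed, plane, idx), **overrides,
            )
            sample = generate_phantom(spec)
            Image.fromarray(sample.image).save(out / f"images/{split}/{stem}.png")
            write_yolo_labels(out / f"labels/{split}/{stem}.txt", sample.labels,
                              image_size)
            planes_map[stem] = plane
            splits[split].append(f"images/{split}/{stem}.png")

    manifest = {
        "path": str(out),
        "names": list(CLASS_NAMES),
        "train": sorted(splits["train"]),
        "val": sorted(splits["val"]),
        "planes": planes_map,
        "image_size": image_size,
    }
    mpath = out / "data.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_manifest(path) -> dict:
    with open(path) as fh:
        m = yaml.safe_load(fh)
    if list(m["names"]) != list(CLASS_NAMES):
        raise ValueError(
            "manifest class list does not match the canonical class table: "
            f"{m['names']}"
        )
    return m
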