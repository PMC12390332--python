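"""Training and inference harness binding the detector, the loss, the
phantom datasets and the evaluation metrics."""

from __future__ import annotations

import csv
import logging
import subprocess
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .metrics import EvalReport, evaluate
from .model import ArchitectureConfig, FBStrNet, save_checkpoint
from .model.decode import decode_predictions
from .model.loss import DetectionLoss
from .phantom import load_manifest, read_yolo_labels
from .postfilter import Detection

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published setup)."""

    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 300
    image_size: int = 640
    momentum: float = 0.937
    iou_threshold: float = 0.41  # training-era assigner IoU hyperparameter
    anchor_threshold: float = 5.0
    batch_size: int = 8
    seed: int = 0
    optimizer: str = "SGD"  # SGD (published setup) or Adam (fast desk-scale)
    loss_name: str = "SIoU"
    theta: float = 4.0
    warmup_epochs: int = 3
    cosine_lr: bool = True
    final_lr_fraction: float = 0.1
    autoanchor: bool = False
    flip_lr: bool = True
    ema: bool = True
    ema_decay: float = 0.998
    box_gain: float = 0.05
    obj_gain: float = 1.0
    cls_gain: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class YoloDataset:
    """In-memory dataset over a YOLO-layout manifest (images + txt labels)."""

    def __init__(self, manifest_path, split: str, image_size: int):
        m = load_manifest(manifest_path)
        root = Path(manifest_path).parent
        self.image_size = image_size
        self.items: list[tuple[str, np.ndarray, np.ndarray]] = []
        self.planes: dict[str, str] = m.get("planes", {})
        for rel in m[split]:
            img_path = root / rel
            stem = img_path.stem
            lbl_path = root / rel.replace("images/", "labels/").replace(".png", ".txt")
            img = Image.open(img_path).convert("L")
            if img.size != (image_size, image_size):
                img = img.resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float32) / 255.0
            # grayscale replicated to the 3-channel stem
            chw = np.repeat(arr[None], 3, axis=0)
            labels = read_yolo_labels(lbl_path, image_size)
            rows = np.array(
                [
                    [
                        0.0, d.cls,
                        (d.x1 + d.x2) / 2 / image_size, (d.y1 + d.y2) / 2 / image_size,
                        (d.x2 - d.x1) / image_size, (d.y2 - d.y1) / image_size,
                    ]
                    for d in labels
                ],
                dtype=np.float64,
            ).reshape(-1, 6)
            self.items.append((stem, chw, rows))

    def __len__(self):
        return len(self.items)

    def ground_truth(self) -> dict[str, list[Detection]]:
        s = self.image_size
        out = {}
        for stem, _, rows in self.items:
            dets = []
            for _, cls, cx, cy, w, h in rows:
                dets.append(Detection(
                    (cx - w / 2) * s, (cy - h / 2) * s,
                    (cx + w / 2) * s, (cy + h / 2) * s, 1.0, int(cls),
                ))
            out[stem] = dets
        return out

    def batches(self, batch_size: int, rng: np.random.Generator | None = None,
                flip_lr: bool = False):
        """Shuffled minibatches; optional random horizontal flip (p = 0.5)."""
        idx = np.arange(len(self.items))
        if rng is not None:
            rng.shuffle(idx)
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo : lo + batch_size]
            imgs = np.stack([self.items[i][1] for i in sel])
            targets = []
            for bi, i in enumerate(sel):
                rows = self.items[i][2].copy()
                rows[:, 0] = bi
                if flip_lr and rng is not None and rng.uniform() < 0.5:
                    imgs[bi] = imgs[bi, :, :, ::-1]
                    rows[:, 2] = 1.0 - rows[:, 2]
                targets.append(rows)
            yield imgs, np.concatenate(targets, axis=0)


class ModelEMA:
    """Exponential moving average of model weights.

    Averaged weights are markedly more stable at the end of short, noisy
    schedules than the last SGD iterate. The decay ramps up over the
    first ``tau`` updates. Normalization buffers (running statistics) are
    copied through unaveraged.
    """

    def __init__(self, model: FBStrNet, decay: float = 0.998, tau: float = 400.0):
        self.decay, self.tau = decay, tau
        self.updates = 0
        self.params = {k: v.copy() for k, v in model.state_dict().items()}

    def update(self, model: FBStrNet) -> None:
        self.updates += 1
        d = self.decay * (1.0 - np.exp(-self.updates / self.tau))
        for name, value in model.state_dict().items():
            if name.startswith("buf::"):
                self.params[name][...] = value
            else:
                shadow = self.params[name]
                shadow *= d
                shadow += (1.0 - d) * value

    def model(self, arch: ArchitectureConfig) -> FBStrNet:
        out = FBStrNet(arch)
        out.load_state_dict({k: v.copy() for k, v in self.params.items()})
        return out


def fit_anchors(dataset: YoloDataset, seed: int = 0) -> np.ndarray:
    """K-means anchor shapes from the training labels (3 scales x 3 pairs).

    Returns anchors in the 640-reference frame expected by
    ``ArchitectureConfig.anchors`` (they are rescaled to the input size at
    use). Clusters are sorted by area and split across pyramid levels.
    """
    from scipy.cluster.vq import kmeans2

    wh = np.concatenate([rows[:, 4:6] for _, _, rows in dataset.items], axis=0)
    wh_px = wh * dataset.image_size
    rng = np.random.default_rng(seed)
    # cluster in log space: anchor quality is a ratio criterion
    centers, _ = kmeans2(np.log(wh_px), 9, minit="++", seed=rng, iter=50)
    anchors = np.exp(centers)
    anchors = anchors[np.argsort(anchors.prod(axis=1))]
    anchors = np.maximum(anchors, 2.0)  # floor of 2 px
    return anchors.reshape(3, 3, 2) * (640.0 / dataset.image_size)


def _lr_at(cfg: TrainConfig, epoch: int) -> float:
    """Linear warmup then (optionally) cosine decay to a floor fraction."""
    if cfg.warmup_epochs and epoch < cfg.warmup_epochs:
        return cfg.learning_rate * (0.1 + 0.9 * epoch / cfg.warmup_epochs)
    if not cfg.cosine_lr:
        return cfg.learning_rate
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    t = (epoch - cfg.warmup_epochs) / span
    lo = cfg.final_lr_fraction
    return cfg.learning_rate * (lo + (1 - lo) * 0.5 * (1 + np.cos(np.pi * t)))


def _git_describe() -> str:
    try:
        return subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=5,
        ).stdout.strip() or "unknown"
    except Exception:
        return "unknown"


def train(arch: ArchitectureConfig, cfg: TrainConfig, manifest_path,
          out_dir, log_every: int = 1, eval_every: int = 0) -> tuple[FBStrNet, list[dict]]:
    """Train a detector on a YOLO-layout dataset; returns (model, history).

    Writes ``train_log.csv`` (per-epoch loss components and optional
    validation mAP) and a final ``checkpoint.npz`` under ``out_dir``.
    """
    if arch.input_size != cfg.image_size:
        raise ValueError(
            f"architecture input_size ({arch.input_size}) must match training "
            f"image_size ({cfg.image_size})"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nn.seed_init(cfg.seed)
    dataset = YoloDataset(manifest_path, "train", cfg.image_size)
    if cfg.autoanchor:
        from dataclasses import replace as _replace

        fitted = fit_anchors(dataset, cfg.seed)
        arch = _replace(arch, anchors=tuple(
            tuple(tuple(float(v) for v in a) for a in lvl) for lvl in fitted
        ))
        log.info("auto-anchor shapes (px at %d): %s", cfg.image_size,
                 np.round(fitted * cfg.image_size / 640.0, 1).tolist())
    model = FBStrNet(arch)
    criterion = DetectionLoss(arch, anchor_t=cfg.anchor_threshold,
                              box_gain=cfg.box_gain, obj_gain=cfg.obj_gain,
                              cls_gain=cfg.cls_gain)
    if cfg.optimizer.upper() == "SGD":
        opt = nn.SGD(model.parameters(), lr=cfg.learning_rate,
                     momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    elif cfg.optimizer.lower() == "adam":
        opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    ema = ModelEMA(model, decay=cfg.ema_decay) if cfg.ema else None

    log.info("training config: %s | git %s", asdict(cfg), _git_describe())
    history: list[dict] = []
    t0 = time.time()
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(cfg, epoch)
        model.train()
        comps_sum: dict[str, float] = {}
        n_steps = 0
        for imgs, targets in dataset.batches(cfg.batch_size, rng, cfg.flip_lr):
            x = nn.Tensor(imgs)
            preds = model(x)
            loss, comps = criterion(preds, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update(model)
            for k, v in comps.items():
                comps_sum[k] = comps_sum.get(k, 0.0) + v
            n_steps += 1
        rec = {"epoch": epoch, "time": time.time() - t0}
        rec.update({k: v / n_steps for k, v in comps_sum.items()})
        if eval_every and (epoch + 1) % eval_every == 0:
            eval_m = ema.model(arch) if ema is not None else model
            rep = evaluate_model(eval_m, manifest_path, "val", cfg.image_size)
            rec["val_map50"] = rep.map50
        history.append(rec)
        if log_every and epoch % log_every == 0:
            log.info("epoch %d: %s", epoch, {k: round(v, 4) for k, v in rec.items()})

    keys = sorted({k for r in history for k in r})
    with open(out / "train_log.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
    if ema is not None:
        model = ema.model(arch)
    save_checkpoint(model, out / "checkpoint.npz")
    return model, history


def predict(model: FBStrNet, images: np.ndarray, conf_threshold: float = 0.25,
            nms_iou: float = 0.45, batch_size: int = 8) -> list[list[Detection]]:
    """Forward + decode + NMS for a stack of (3, S, S) images."""
    model.eval()
    out: list[list[Detection]] = []
    for lo in range(0, len(images), batch_size):
        x = nn.Tensor(images[lo : lo + batch_size])
        raw = [p.data for p in model(x)]
        out.extend(decode_predictions(raw, model.cfg, conf_threshold, nms_iou))
    return out


def evaluate_model(model: FBStrNet, manifest_path, split: str,
                   image_size: int, conf_threshold: float = 0.001) -> EvalReport:
    """Decode the whole split and compute the detection metrics report."""
    dataset = YoloDataset(manifest_path, split, image_size)
    imgs = np.stack([it[1] for it in dataset.items])
    dets = predict(model, imgs, conf_threshold=conf_threshold)
    dets_by_image = {dataset.items[i][0]: dets[i] for i in range(len(dataset))}
    return evaluate(dets_by_image, dataset.ground_truth())
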