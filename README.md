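# fbstrnet

Lightweight single-stage detection of the twelve key anatomical
structures of the fetal brain in first-trimester ultrasound standard
planes.

## The problem

Between 11 and 14 weeks of gestation, sonographers assess the fetal
brain on four standard ultrasound planes — the trans-lateral-ventricular
axial plane (TLVAP), trans-thalamic axial plane (TTAP),
trans-posterior-fossa axial plane (TPFAP) and mid-sagittal plane (MSP) —
checking a fixed set of structures on each: cranial bone (CB), brain
midline (BM), the paired choroid plexuses (CP), cisterna magna (CM),
brainstem (B), fourth ventricle (FV), aqueduct of Sylvius (AS), thalamus
and cerebral peduncles (T&P), nasal bone (NB), mandible (M), third
ventricle (TV) and hard palate (HP). Speckle noise and low contrast make
this tedious and operator-dependent; a real-time detector that boxes
and names each structure supports screening and training.

`fbstrnet` implements such a detector end to end:

* **Architecture** — a YOLOv5-s skeleton in which the backbone's strided
  convolutions and C3 blocks are replaced by Ghost modules (half the
  channels computed densely, half derived by cheap 5×5 depthwise
  convolutions), and the coupled prediction head is replaced by a
  per-level decoupled head (1×1 stem, parallel classification and
  regression branches of two 3×3 convolutions, an IoU/objectness branch
  on the regression side). At 12 classes the four variants weigh 7.0 M
  (baseline), 5.1 M (Ghost), 8.8 M (decoupled) and 6.8 M (full model)
  trainable parameters.
* **Box loss** — the SIoU regression loss
  `L = 1 − IoU + (Δ + Ω)/2`, whose distance term Δ is sharpened by an
  angle term Λ (0 for axis-aligned centers, 1 at 45°) and whose shape
  term Ω penalizes relative width/height mismatch with exponent θ = 4;
  CIoU is available as the baseline alternative.
* **Clinical post-filter** — each plane can only contain its expected
  structure set (`P_OBJS`); after NMS the filter drops foreign classes,
  keeps the best detection per class above a strict 0.5 confidence
  gate (top two for the paired CP), and returns them sorted by class.
* **Evaluation** — precision, recall, per-class AP (all-point
  interpolated precision-envelope integral), mAP@0.5 and mAP@0.5:0.95.
* **Phantoms** — a deterministic synthetic-ultrasound generator that
  renders each plane's structure set on a fan-shaped field with
  multiplicative speckle, providing images plus exact YOLO-format
  ground truth for training and testing without clinical data.

Everything runs on a self-contained numpy autograd/conv-net layer
(`fbstrnet.nn`) — no GPU framework required — so training sizes are
desk-scale by design. See `docs/methods.md` for the scientific detail.

## Worked example

```python
from fbstrnet import boxes

terms = boxes.siou_loss(gt=(0, 0, 2, 2), pred=(0, 0, 4, 4), theta=4)
print(f"IoU={terms.iou:.2f}  angle={terms.lambda_angle:.1f}  "
      f"dist={terms.delta:.6f}  shape={terms.omega:.6f}  loss={terms.loss:.6f}")
```

prints

```
IoU=0.25  angle=1.0  dist=0.121174  shape=0.047937  loss=0.834556
```

— the prediction doubles the ground-truth box, so a quarter of it
overlaps (IoU 0.25), the centers sit at exactly 45° (angle term 1),
and the distance and shape penalties contribute (0.121 + 0.048)/2 on
top of 1 − 0.25.

A miniature end-to-end run (generate phantoms, train a reduced-width
model, evaluate, and apply the plane filter):

```bash
fbstrnet make-phantoms data/ --n-per-plane 20 --image-size 128 --seed 0
fbstrnet train data/data.yaml --image-size 128 --epochs 50 \
    --batch-size 8 --learning-rate 0.08 --out-dir runs/demo
fbstrnet eval runs/demo/checkpoint.npz data/data.yaml
fbstrnet detect runs/demo/checkpoint.npz data/images/val --plane auto
fbstrnet count-params --ghost --decoupled
```

`count-params` for the full model prints

```json
{
  "total": 6866453,
  "millions": 6.8,
  "by_component": {"backbone": 2237208, "neck": 2834688, "head": 1794557}
}
```

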