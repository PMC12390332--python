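# Methods

This note documents the models, conventions and numerical choices behind
`fbstrnet`, and what its synthetic experiments do and do not show.

## The detection model

The detector is a single-stage, anchor-based convolutional network on
the YOLOv5-s skeleton (depth multiple 0.33, width multiple 0.50): a
strided backbone with feature taps at strides 8/16/32, a PANet neck, and
a three-level prediction head with three anchors per level. Two
substitutions define the full model:

**Ghost backbone.** Each of the four strided downsampling convolutions
after the stem is replaced by a GhostConv, and each of the four backbone
C3 blocks by a C3Ghost whose bottlenecks are rebuilt from Ghost modules.
A Ghost module produces half its output channels with a dense primary
convolution and derives the other half with a cheap 5×5 depthwise
convolution ("cheap linear operation"), concatenating the two halves.
For odd widths the intrinsic half rounds up. The stem, the SPPF block
and the neck are left dense.

**Decoupled head.** Per pyramid level, a 1×1 stem reduces the channel
count to the head width, then two parallel branches of two stacked 3×3
convolutions handle classification and box regression separately; an
IoU/objectness 1×1 prediction is appended to the regression branch. The
head remains anchor-based and per-level (no weight sharing across
levels); the IoU branch plays the objectness role of the standard
YOLOv5 assignment and loss.

### Parameter budgets and the head width

Model size is reported in millions of trainable parameters truncated to
one decimal; this is the convention under which the four reference
budgets of the ablation family are internally consistent (rounding to
nearest would report the baseline at 7.1 and the full model at 6.9).
The budgets the construction reproduces at 12 classes:

| variant                    | parameters | millions |
|----------------------------|-----------:|---------:|
| baseline (coupled, dense)  |  7,051,993 |      7.0 |
| Ghost backbone only        |  5,117,745 |      5.1 |
| decoupled head only        |  8,800,701 |      8.8 |
| Ghost + decoupled (full)   |  6,866,453 |      6.8 |

The published head description names a nominal stem width of 256, which
after the 0.50 width multiple suggests 128 channels; at 128 the head
adds 1.86 M parameters, overshooting the reference budget (8.8 M total)
by ~0.11 M. The default `head_hidden_channels = 124` is the effective
width pinned by the budgets themselves (adds 1.75 M; both the 8.8 M and
6.8 M variants then reproduce exactly, and rounding the full model to
nearest gives the 6.9 M figure that also circulates for it). The width
is an exposed config field; nothing else in the package depends on its
default.

## Box losses

The box-regression loss is selectable between CIoU (the stock YOLOv5
choice) and SIoU. SIoU decomposes the mismatch between a predicted box
and its ground truth into four parts:

* IoU — ordinary overlap;
* angle Λ = 1 − 2 sin²(arcsin(a_h/σ) − π/4), where σ is the distance
  between box centers and a_h its vertical component: 0 when the centers
  are axis-aligned, 1 at 45°;
* distance Δ = Σ_{t∈{x,y}} (1 − e^{−γρ_t}) with ρ_t the squared center
  offset normalized by the smallest enclosing box and γ = 2 − Λ (the
  angle term sharpens the distance penalty);
* shape Ω = Σ_{t∈{w,h}} (1 − e^{−ω_t})^θ with ω_t the relative
  width/height mismatch.

Total: L_SIoU = 1 − IoU + (Δ + Ω)/2. Conventions worth noting:

* The division by 2 applies to the sum (Δ + Ω); this is what makes the
  loss vanish for a perfect match.
* The symbol pair c_h (enclosing-box height, used in ρ_y) and a_h
  (vertical center offset, used in Λ) are distinct quantities and both
  are reported in `SIoUTerms`.
* θ is exposed with default 4 (the value recommended where the loss was
  introduced); it controls how much attention the shape term receives.
* Degenerate σ = 0 (coincident centers) takes a_h/σ := 0, hence Λ = 0 —
  the continuity limit along any axis-aligned approach; implemented as
  division by max(σ, ε) so the exact axis-aligned cases stay exact. The
  arcsin argument is clamped to [0, 1] against floating rounding.
* Boxes are continuous pixel coordinates (area = (x2−x1)(y2−y1)),
  origin top-left, y downward.

The same formula code runs in two regimes: plain numpy for analysis and
evaluation, and the package's autograd tensors inside the training loss
(the core is written against a swappable ops namespace, so there is a
single source of truth for the math).

## Training objective and assignment

Standard YOLOv5 recipe: ground-truth boxes are assigned on every level
to anchors whose width/height ratios fit within the anchor threshold
(default 5.0), at their own grid cell plus up to two neighboring cells.
The loss sums a box term (CIoU or SIoU on positives), an objectness
binary cross-entropy whose target is the achieved IoU (balance weights
4/1/0.4 across levels), and a per-class binary cross-entropy, with
gains 0.05/1.0/0.5. The `iou_threshold = 0.41` setting is retained in
`TrainConfig` as the training-era assigner hyperparameter it appears to
be; it does not drive the NMS, whose IoU threshold defaults to 0.45.

Weight averaging (EMA, decay 0.998 with a 400-update ramp) is kept
during training and the averaged weights are the ones saved and
evaluated; at short schedule lengths the averaged iterate is much more
stable than the last SGD step. An optional k-means anchor refit from
the training labels is available (`autoanchor`), off by default — on
the phantom task the redundant default anchors give each structure more
positive matches and train better.

## Numerical stack

No GPU framework is used: the package carries a small reverse-mode
autograd engine over numpy (im2col/GEMM convolutions, explicit-formula
batch-norm backward, scatter-based pooling gradients), verified against
central finite differences in the test suite. This bounds the practical
problem sizes: training runs here are desk-scale by design.

## Evaluation

A detection is a true positive at IoU threshold t if it is the
highest-confidence detection claiming an unmatched same-class ground
truth with IoU ≥ t; matching is greedy in descending confidence, one
detection per ground truth. AP integrates the precision envelope over
recall with all-point interpolation (a 101-point COCO-style variant is
behind a flag); mAP@0.5 averages classes at t = 0.5 and mAP@0.5:0.95
over the ten thresholds 0.50:0.05:0.95. Classes with no ground truth in
the split are excluded from the mean and logged. Headline precision and
recall are read at the per-class maximum-F1 operating point, since the
evaluated operating point is otherwise unspecified. Evaluation decodes
at a low confidence floor (0.001) so the full ranking enters the AP
integral.

## Plane-aware post-filter

First-trimester screening uses four standard planes with fixed expected
structure sets (P_Objs): TLVAP {CB, BM, CP}, TTAP {CB, BM, AS, T&P},
TPFAP {CB, CM, B, FV}, MSP {CB, CM, B, FV, NB, M, TV, HP}. After NMS
the filter (1) drops classes foreign to the plane, (2) keeps the single
best detection per class among those with confidence strictly above
0.5, (3) keeps the top two for the paired choroid plexus, and (4)
deduplicates exact records and sorts by class index. The gate is strict
(> 0.5) and exposed as a parameter; the output is always a subset of
the input records. Class indices follow the canonical table order
CB, BM, CP, CM, B, FV, AS, T&P, NB, M, TV, HP.

The plane identity is assumed known at inference (it is in clinical
use); `infer_plane` is a documented stopgap that scores each plane by
matched-minus-foreign detected classes, breaking ties toward the
smaller expected set and then a fixed plane order.

## Phantoms: what they emulate and what they don't

The phantom generator renders schematic versions of the four planes on
a fan-shaped sector field: a bright elliptical skull ring, a midline
echo, paired bright choroid plexuses, hypoechoic fluid spaces, paired
thalami/peduncles, a brainstem region and short bright bone echoes —
exactly the class composition each plane expects (with CP twice in
TLVAP). Smoothed multiplicative Rayleigh noise and a light Gaussian
blur emulate speckle and low SNR. Placement, size and rotation are
jittered per image; every image is a pure function of its seed (derived
per image from a SHA-256 of (seed, plane, index), so datasets are
reproducible across platforms).

The phantoms are deliberately schematic: intensity distributions,
acoustic shadowing, probe geometry and anatomical variability of real
ultrasound are not modeled. Passing the end-to-end tests therefore
demonstrates that the pipeline (rendering → labels → assignment →
training → decoding → NMS → plane filter → mAP) is correct and
learnable — not that the detector would reach clinical accuracy on real
images.

## Desk-scale smoke configuration

The end-to-end check trains the full model (Ghost + decoupled + SIoU)
at reduced scale chosen for a single CPU: width multiple 0.25, head
width 32, 128×128 inputs, 360 training and 40 held-out phantoms (90 +
10 per plane), batch 8, 35 epochs of SGD (lr 0.08, cosine schedule
with 3 warmup epochs, weight decay 5e-4), horizontal-flip
augmentation, EMA weights evaluated. The bar is held-out mAP@0.5 ≥ 0.5
and ≤ 4 plane-filtered detections on TLVAP images. Generalization at
this scale is data-limited, not update-limited: many distinct phantoms
with few epochs clearly beats the reverse split of the same compute
(small-dataset/many-epoch runs reach ~0.9 mAP on their training split
while oscillating around ~0.5 held-out).

## Known limitations

* The numpy training stack is orders of magnitude slower than a GPU
  framework; full-resolution (640×640) training is out of practical
  reach here.
* Thin or very small structures (brain midline, aqueduct) sit at the
  edge of detectability at the smoke scale's 128-pixel resolution;
  their AP dominates the variance of the end-to-end metric.
* The NMS/assigner interpretation of the 0.41 IoU setting is ambiguous
  in the source material; it is kept as an assigner-era constant and
  not used by NMS.
* `infer_plane` is a heuristic; real deployments know the plane.
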