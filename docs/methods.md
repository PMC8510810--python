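# Methods

## Problem and approach

Mitotic count per unit tumour area is a core component of breast-cancer
grading, but public mitosis datasets are mostly *weakly* labelled: each
mitosis is annotated by a single centre point, which is not enough to
train a modern object detector directly. This package implements a
two-phase remedy:

1. **Weak-to-strong label generation.** A U-shaped segmentation network
   is trained on tiles that do carry pixel-level masks. Its predicted
   mitosis-probability map is thresholded, split into 8-connected
   components, and each component's minimum circumscribed axis-aligned
   rectangle becomes a bounding-box "strong" label. A box is positive
   iff a weak centre point falls inside it; boxes containing no point
   are segmentation false positives and are kept as negative candidates,
   while points falling in no box are reported as unmatched (never
   turned into fabricated boxes).
2. **Detection.** An R-CNN-style detector is trained on the generated
   boxes: region proposals, CNN features on fixed-size warped crops,
   linear-SVM region classification, and bounding-box regression, with
   training minibatches of exactly 32 positive and 96 negative regions.

Scoring follows the ICPR mitosis-contest protocol: a detection is
correct when the diagonal intersection of its box lies within 8 µm of an
unclaimed ground-truth point; precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2RP/(R+P).

## Segmentation network

The encoder alternates CNN blocks with single-level 2-D discrete wavelet
transform (DWT) downsampling; the decoder mirrors it with the inverse
transform (IWT) and channel-wise skip concatenation, ending in a 1×1
projection to K = 2 class channels. Each CNN block is a 4-layer fully
convolutional stack of 3×3 convolution + batch normalization + ReLU, no
pooling. The DWT replaces pooling: it halves resolution while retaining
all frequency content in four subbands stacked channel-wise (C → 4C), so
the down/upsampling pair is exactly invertible.

Wavelet choice: orthonormal Haar by default (periodization boundary
handling), configurable to any orthogonal PyWavelets filter. With an
orthonormal transform the adjoint equals the inverse, which gives the
backward pass of the wavelet layers for free and makes energy
conservation testable (sum of squared coefficients equals sum of squared
inputs).

Loss: pixelwise softmax cross entropy, E = −∑ₓ log p_{l(x)}(x) where
p_k(x) is the per-pixel softmax and l(x) the true class. The sum-form of
the objective without the minus sign would be *maximised* at the
optimum; the implementation uses the standard negative-log-likelihood
sign so that minimisation drives the true-class probability toward 1
(the operation `pixelwise_cross_entropy` returns the total; the trainer
optimises the per-pixel mean so the learning rate is independent of tile
size).

Training: Adam, batch size 8, 100 epochs by default, with the learning
rate decaying log-linearly from 1e−3 at the first epoch to 1e−6 at the
last (these are also the endpoints of the schedule regardless of epoch
count). Inputs of odd or non-multiple size are reflect-padded to the
next multiple of 2^levels and cropped back after decoding, so output
spatial shape always equals input shape. Class 0 is background, class 1
mitosis; no per-pixel class weighting is applied by default.

All network code (convolution via im2col, batch norm, ReLU, max pool,
dense layer, Adam) is a small NumPy layer library in `mitodet._nn`,
float64 throughout, fully deterministic for a fixed seed. Checkpoints
are `.npz` archives holding weights, batch-norm running statistics and
the architecture description.

Architecture numerics not fixed by the design (level count, channel
widths, skip style) default to levels = 3, channels = (32, 64, 128),
skip connections by concatenation; all are config-exposed. Desk-scale
runs in the tests and the acceptance script use levels = 2, channels =
(8, 16), 80 epochs with lr floor 1e−4 — with only ~160 optimizer steps
the log-linear decay to 1e−6 would spend most of the run below a useful
step size, so the short-run floor is raised; the schedule shape is
unchanged.

## Label generation parameters

Binarization threshold 0.5 (≥ convention at the boundary), minimum
component area 5 px (threshold speckle removal), both config-exposed.
Point-in-box is boundary-inclusive on the closed pixel extent
[x0, x1−1] × [y0, y1−1]. When a point lies inside several boxes it is
assigned to the box with the nearest centre, ties broken by smaller
area, then insertion order — deterministic and documented. Rectangles
are axis-aligned (the format every downstream detector consumes), not
rotated. Coordinates are 0-based, x = column, y = row, boxes half-open
[x0, x1) × [y0, y1), identical in memory and in every file format.

## Detector

* **Proposals.** Two methods: `selective_search` — Felzenszwalb
  graph-based over-segmentation followed by greedy hierarchical region
  merging scored by colour-histogram intersection + size + fill (the
  texture channel of classic selective search is omitted; at mitosis
  scale it adds little) — and `sliding_window`, multi-scale square
  windows (default sizes 8/12/16/24 px, stride = size/2), fully
  deterministic and the default for small-scale runs.
* **Labeling.** Max-IoU against ground truth: ≥ 0.5 positive, < 0.3
  negative, in between discarded. Ground-truth boxes join the proposal
  set during training, as in the original R-CNN recipe.
* **Features.** Proposals are warped to 64×64 in full-scale configs and
  32×32 at desk scale, passed through a small 3-stage conv-BN-ReLU-pool
  CNN trained with a softmax head on 32/96 minibatches (Adam, constant
  1e−3).
* **Classifier.** Linear SVM (C = 1, primal) on the frozen CNN features;
  confidences are the logistic of the SVM margin. A softmax-head
  classifier is available behind `classifier: softmax`.
* **Box regression.** Ridge regression from positive-region features to
  the standard centre/log-size offsets (dx, dy, dw, dh); encode/decode
  is an exact inverse pair. Regression is applied at inference by
  default and can be disabled.
* **Post-processing.** Score threshold 0.5, greedy NMS at IoU 0.3,
  output sorted by descending confidence. Hard-negative mining is off by
  default.

## Evaluation protocol

The match radius is 8 µm converted to pixels by the scan resolution
(e.g. 32 px at 0.25 µm/px). Matching is one-to-one and greedy: in
descending confidence order each detection claims its nearest unclaimed
ground-truth point within the radius. Conservation (TP+FN = #gt,
TP+FP = #detections) holds by construction. Greedy matching is the
convention of the mitosis contests but is not guaranteed optimal: a
high-confidence detection can claim the only point reachable by a later
detection. Across 200 random small instances in the acceptance suite
this occurs exactly once (pinned as a regression case); an exhaustive
optimal assignment agrees on all others. Undefined precision (no
detections) is reported as 0 with a `precision_defined=False` flag so
batch evaluation never aborts. Counts are pooled across tiles by
default; per-tile macro-averaging is a trivial caller-side variant.

## Synthetic data

The generator emulates exactly the structure the pipeline consumes: a
pink, lightly textured eosin-like background (mean RGB (228, 192, 214),
smooth Gaussian texture, pixel noise sd 7); dark hyperchromatic mitotic
figures (mean RGB (72, 40, 98)) as perturbed ellipses with semi-axes
2.5–5 px and low-order harmonic boundary irregularity 0.25; and lighter
distractor nuclei (mean RGB (158, 118, 176)) that are absent from the
mask. Placement is rejection sampling with a minimum boundary gap of
3 px, which guarantees each mitosis is its own 8-connected component, so
boxes and centroid weak labels are exact by construction. Weak labels
are component centroids (snapped to the nearest component pixel if the
centroid of a concave blob strays), optionally jittered.

Default study conditions for the end-to-end runs: 16 training + 4
validation tiles of 64×64 px at a nominal 0.25 µm/px, 2–4 mitoses per
tile, ~3 % foreground. Tile and per-stage seeds fan out from one global
seed by fixed offsets, so every stage is independently reproducible.

What passing on this data does **not** show: robustness to stain
variation, chromatin texture, overlapping or out-of-focus figures,
scanner differences, or the extreme foreground rarity of real slides
(~10 mitoses per 2000×2000 view). The synthetic contrast between mitosis
and distractor colour is far cleaner than real H&E; results here
validate the pipeline's mechanics, not clinical performance.

## Numerical choices and degenerate inputs

* Wavelet layers require even spatial sizes; callers pad (reflect),
  never crop. Dimension errors name the offending axis.
* Softmax is shift-invariant (per-pixel max subtracted); NaN activations
  raise.
* Cross entropy clips probabilities at 1e−300 before the log.
* Empty proposal sets, empty detection lists and all-background tiles
  are legal everywhere downstream; empty positive or negative pools for
  minibatch sampling raise a named error.
* Minibatch sampling uses replacement only when a pool is smaller than
  its quota.
* Box CSV readers validate x1 > x0, y1 > y0 and report the offending
  line number.

## Known limitations

* Pure-NumPy training is CPU-bound; the defaults are sized for
  desk-scale experiments (minutes), not for contest-scale datasets.
* Selective search implements colour/size/fill similarity only.
* Merged (touching) mitoses are flagged as one component, not split.
* The greedy matcher's rare sub-optimality (above) slightly understates
  TP in adversarial geometries.
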