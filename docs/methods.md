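# Methods

This note documents the models and procedures implemented in `lynodet`, the
choices made where the design space was genuinely open, and what the
package's synthetic experiments do and do not demonstrate.

## The detector

The detector is a single-stage, anchor-free convolutional network in the
YOLOv8 family, modified in three ways relative to the nano-scale reference
layout: every stride-2 downsampling convolution uses a 7×7 kernel instead
of 3×3; the backbone is deepened to six stride-2 stages so that channel
depth grows 64 → 128 → 256 → 512 → 1024 → 2048; and the feature pyramid is
extended by a P6 level at stride 64, with the three detection heads moved
to strides 16/32/64. At a 640×640 input the stage outputs are 320², 160²,
80², 40², 20² and 10² pixels. C2f blocks (split, n residual bottlenecks of
two 3×3 convolutions, concatenation of all streams, 1×1 fusion) refine the
features between downsampling steps with repeat counts 3/6/6/3, and an SPPF
block (1×1 reduce, three chained 5×5 stride-1 max-pools, concat, 1×1 fuse)
terminates the backbone. Each conv block is Conv → BatchNorm → SiLU.

Resolved ambiguities, recorded as the package's own decisions:

- **Padding.** The published output shapes require shape-preserving padding
  for the 7×7 stride-2 convolutions, so padding is `k//2 = 3` throughout;
  a padding of 1 would not reproduce the 320×320 first-stage output.
- **7×7 scope.** The enlarged kernel applies to the standalone downsampling
  convolutions only; C2f bottleneck convolutions stay 3×3, since only the
  Conv rows of the published table carry the 7×7 annotation.
- **Three heads, not four.** The neck names exactly Detect1–3, so the
  three-head PAN-FPN is grafted onto the three deepest scales (16/32/64)
  rather than a four-head P3–P6 reading. The pyramid levels are
  configuration, not code.
- **Ablation axis.** `baseline` is the standard five-stage nano layout
  (16–256 channels, 3×3, heads 8/16/32); `kernel7` widens its kernels to
  7×7; `hyper` is architecturally identical to `kernel7` (it is a
  hyperparameter-only ablation, which is why the two share a FLOP count);
  `extraconv` is the deepened six-stage topology at half channel width;
  `full_p6` is the full 64–2048 configuration. This yields the strict cost
  ordering baseline < kernel7 = hyper < extraconv < full_p6. Absolute GFLOP
  values depend on the counting convention (here: 2 × conv
  multiply–accumulates, batch-norm folded, activations ignored) and are not
  treated as a contract; the ordering is.
- **Head internals.** Two 3×3 conv blocks followed by one 1×1 convolution
  emitting `4·reg_max` box-distribution logits and `num_classes` class
  logits per cell, with `reg_max = 16`. The final convolution is
  initialized near zero with a class bias of −4.6 (≈1 % prior positive
  rate); starting from calm predictions instead of Kaiming-scale noise
  removed large seed-to-seed variance in early training.
- **Weight init.** Kaiming-normal for convolutions, unit/zero for norm
  layers, all drawn from a single seeded generator.

## Training

Hyperparameters follow the published configuration: Adamax (β₁ = 0.937,
β₂ = 0.999), learning rate 5e-3 with lr0 = lrf read as a constant schedule,
weight decay 5e-4 on convolution weights, batch size 16, 640×640 default
input, mosaic augmentation deliberately off. A one-epoch linear warmup from
0.1× the learning rate is applied (disable by setting `warmup_epochs = 0`);
early stopping is available as optional patience but off by default, since
no stopping rule is part of the training specification.

Targets are built by a task-aligned assigner: among cells whose centers
fall inside a ground-truth box, the top-10 by `cls^0.5 · IoU^6` are
positive; a cell claimed by several boxes goes to the one with higher IoU;
class targets are the alignment scores normalized so their peak equals the
box's best IoU. Losses: 1 − CIoU on positive cells (IoU-weighted mean),
distribution-focal cross-entropy on the two integer bins flanking each
edge distance, and binary cross-entropy over all cells, combined with
gains 7.5/0.5/1.5. The assigner operates on detached predictions, so the
gradient check in the test suite freezes the assignment before comparing
backpropagation with central finite differences (agreement within 1e-3
relative on float64).

Inference decodes the expected value of each edge distribution, applies
per-class greedy NMS (evaluation defaults: confidence 0.001, NMS IoU 0.7,
at most 300 detections) and clips boxes to the image.

Everything runs on a purpose-built numpy reverse-mode autodiff engine
(`lynodet.autodiff`): strided im2col convolution, fused batch
normalization, SiLU, same-size max pooling, nearest-neighbour upsampling,
softmax families and a stable binary cross-entropy, each primitive with a
hand-written backward verified against finite differences. Input sizes
should be multiples of the deepest head stride so the neck's upsample /
concat geometry closes; batch-norm running statistics use momentum 0.1 and
are part of the checkpoint.

## Dataset protocol

Labels are darknet text lines (`class cx cy w h`, normalized; a sixth
column carries confidence in prediction files) written at six decimals so
text round-trips are lossless. Splits are stratified by the class of each
image's first box — a documented simplification, since images may contain
up to three classes — with largest-remainder rounding (1931 ids split
80/10/10 gives 1545/193/193). K-fold assignment deals shuffled strata
round-robin in a single pass, so folds differ by at most one id globally
and per class.

Augmentation (horizontal/vertical flip, ±45° rotation, brightness
±40 %, zoom 0.5–1.5×) applies to training records only, either on the fly
(the training default) or as an offline expansion with multiplier 3; both
modes exist because the protocol describes on-the-fly augmentation while
also reporting a fixed post-augmentation count. Rotated boxes are
re-enclosed axis-aligned from their rotated corners, clipped to the frame,
and dropped when clipping removes more than 90 % of the re-enclosed area —
a threshold chosen for label sanity and exposed as a constant. Every
augmented record carries provenance (origin id plus the op trace), and the
auditor reports any augmented record in val/test and any training record
whose origin lies in val/test. Class balancing keeps 168 images per class
(configurable), reports shortfall classes instead of failing, and the
normal-class count defaults to 170 where two published figures (192 vs 170)
disagree.

## Evaluation

Matching is greedy and one-to-one within each class of each image:
detections in descending confidence take the highest-IoU unmatched ground
truth at IoU ≥ 0.5 (ties: higher IoU, then earlier index). AP uses the
101-point interpolation of the monotone precision envelope; all-point
integration is available behind a flag. P/R/DSC for report rows are taken
at the confidence threshold maximizing pooled F1 — an operating-point
convention the source analysis leaves unstated. The "Total" row averages
only classes with at least one ground truth and one prediction, which is
what makes 13-of-15-class totals well defined when two classes are never
predicted; counting undetected classes as AP 0 is available behind a flag,
and the choice between the two is left to the caller because the published
totals rule is not derivable from the printed tables. The confusion matrix
matches predictions to ground truths greedily across classes at confidence
0.25 / IoU 0.45 (also configurable) and books unmatched ground truths and
predictions against the background row/column.

## Statistics

Given one row per detector (precision, recall, mAP50, DSC), the module
computes per-column mean, n−1 standard deviation, Student-t 95 % CI, a
two-sided one-sample t-test against a per-column baseline, Cohen's
d = (mean − μ₀)/sd and Shapiro–Wilk normality (scipy's Royston
approximation). The prose of the source analysis swaps the
"precision"/"recall" labels relative to its own table; this module keys
every statistic by column identity, under which the baselines 0.80
(precision), 0.78 (recall) and 0.82 (mAP50) reproduce all printed values
at four decimals. A second, method-unstated CI set printed in the source
("comparing models") does not match the t-based intervals and is not
reproduced. Constant columns yield NaN test statistics but still rank.

## Synthetic fixtures: what they show and what they don't

The generator emulates the statistical structure of the clinical dataset,
not its radiology: a grayscale torso-shaped background with Gaussian noise,
bright warm-colormap ellipses as "uptake", one to three instances per
image, class determined by anatomical zone (cervical top-center, axillary
upper-sides, inguinal bottom, retroperitoneal inside the abdominal region,
…) and by a per-station ellipse aspect ratio. Left/right stations share
their base station's shape so they remain distinguishable by position only
— the axis the confusability knob manipulates by sliding paired zones
together (level 0 unchanged, level 1 coincident). The per-station aspect
cue exists because class identity must be learnable by a translation-
invariant CNN: with position as the only cue, absolute location reaches
the network only through padding boundary effects, which proved an
unreliable signal at desk scale.

Default counts mirror the real class structure: 168 images per class,
normal 170, and the two deliberately rare classes at their real instance
counts (nose 14, retroperitoneal 9). Desk-scale experiments use a
downscaled regime chosen once: 64×64 images, the `baseline` topology at
width 0.25 (~250 k parameters), 30 epochs, batch 16 — small enough that
the full test suite, including four training runs, completes in about
three minutes on one CPU. The smoke benchmark trains on an easy
two-class, 200-image set without augmentation (the benchmark isolates the
optimizer and losses; augmentation robustness is tested separately) and
reaches validation mAP50 ≥ 0.90 in at least two of three seeds. The
rare-class experiment keeps nose/retroperitoneal at 14/9 against four
common classes at 50 and reproduces the qualitative published failure
mode: the two rare classes rank last in per-class AP. These results
validate the pipeline's mechanics and the direction of its effects; they
say nothing about clinical detection performance, which requires the
private dataset and GPU-scale training and is consumed here only as the
printed comparison table.

## Known limitations

- The autodiff engine is single-threaded numpy; the full-width `full_p6`
  model (~490 M parameters) is buildable and traceable but not practically
  trainable in this package — cost accounting is therefore symbolic.
- Stratification uses the first box's class only.
- The fixture appearance model is non-clinical by design; no SUV
  simulation, DICOM handling or PET/CT fusion is attempted.
- `predict` resizes rectangular inputs to the square training size rather
  than letterboxing.
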