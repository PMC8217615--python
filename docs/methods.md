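# Methods

## Problem and model

Some bacteria — notably *Candidatus* Thiosymbion — divide along their long
axis instead of across it: a dividing cell widens rather than elongates, and
a septum forms along the major axis. Counting such cells in phase-contrast
micrographs is usually manual. This package automates the classification of
single-cell images into two classes, `longitudinal_division` (class 0) and
`other_division` (class 1), with a residual network, and provides every
stage around it: synthetic data generation, cell extraction, partitioning,
augmentation, training, and evaluation.

The classifier is a ResNet-18: a 7×7/2 stem convolution, batch
normalization and ReLU, a 3×3/2 max pool, four stages of two basic residual
blocks (widths 64/128/256/512), global average pooling and a 2-way fully
connected head. Each basic block computes `y = relu(x + f(x, w))` where
`f` is conv3×3–BN–ReLU–conv3×3–BN; when a stage halves resolution and
doubles width, the skip path is a 1×1 strided projection convolution + BN
so shapes agree. Convolution is cross-correlation (no kernel flip): each
output pixel is the inner product of the kernel with its receptive region,
swept left-to-right, top-to-bottom at a fixed stride; a k×k kernel on an
n×n image at stride s yields a `floor((n−k)/s)+1` square feature map.

The entire network, its backward pass, and the optimizer are implemented in
NumPy (float32, im2col + GEMM convolutions). Correctness of the backward
pass was established against central-difference directional derivatives in
float64 (relative error ~1e−8 on the full network).

## Optimization

Training uses minibatch SGD with momentum in velocity form:

    v ← μ·v + α·ḡ,    θ ← θ − v

with ḡ the minibatch-averaged gradient of the 2-class cross-entropy on the
head scores. There is no dampening, Nesterov term, or weight decay. The
learning rate follows a step schedule, `α(epoch) = α₀·γ^⌊epoch/period⌋`
(0-based epochs, so decays take effect entering epochs 7, 14, 21 at the
defaults). Full-scale defaults: 25 epochs, batch 16, α₀ = 0.001, μ = 0.9,
period 7, γ = 0.1. All layers remain trainable when fine-tuning from a
checkpoint.

Epoch-level loss and accuracy sums optionally flow through a compensated
(Kahan) accumulator: `T=S; U=x+R; S←S+U; R←U−(S−T)`, which carries the
rounding residual and gives near-double-precision totals in single
precision. Note that this plain recursion cannot recover an addend whose
residual is later overwhelmed by a much larger cancelling term (Neumaier's
variant would); the tests demonstrate the recovery property on streams the
recursion does handle.

Best-model selection: the weight snapshot with the highest validation
accuracy, earliest epoch on ties. Validation and test passes use the
deterministic eval transform (resize + normalize only) so reported metrics
are reproducible; random augmentation at evaluation time would make them
stochastic.

## Synthetic data: what it emulates and what it does not

The generator renders dark capsules (rounded-end rods) on a light noisy
background, following the phase-contrast convention (an `invert` flag
covers bright-on-dark dialects). Class geometry:

- class 0: width/length ratio sampled in (0.55, 0.80) with a darker
  *axial* septum line — dividing cells widen instead of elongating;
- class 1: ratio in (0.20, 0.45); half the cells carry a transverse septum;
  a quarter carry a "very narrow crease" (1–2 px transverse indentation),
  the adversarial feature that can tempt a classifier toward class 0.

Defaults: 256×256 canvas, 3–6 cells per image, background level 0.85,
Gaussian noise sd 0.03 (intensity units in [0,1]), cell intensity
0.15–0.35, cell length 24–40 px, orientation uniform in [0, π). Cells are
placed by rejection sampling so their 2 px-inflated boxes never overlap:
the extraction step labels touching cells as one component, which would
corrupt labels. Geometry values were chosen for class separability and
plausible rod proportions; the source micrographs' pixel scale is unknown,
so no physical calibration is claimed.

Not emulated: phase-contrast optics (halo, shade-off), focus drift, debris,
touching or overlapping cells, intensity gradients, or the natural
morphology continuum between classes. Passing tests on this data therefore
show the pipeline's machinery is correct and that the network can learn
shape/septum cues — not that the trained weights transfer to real
micrographs.

## Extraction

Binarization defaults to Otsu's threshold from the image's own histogram
(parameter-free and standard for bimodal microscopy histograms), with a
fixed-value override; a constant image under Otsu raises an error advising
a fixed threshold. Components use 8-connectivity by default, ids assigned
in raster-scan order of first pixel. Groups smaller than `min_area`
(default 50 px²) are ignored — the area threshold is "a priori" by design.
Boxes are tight, 0-based, half-open; crops keep original grayscale
intensities (binarization is used only to localize) and are padded by 2 px,
clipped to image bounds.

## Partitioning and augmentation

33% of each class is held out for testing, then 20% of the remainder for
validation, with *ceiling* rounding on held-out counts — the convention
verified to yield the reference per-class subset sizes exactly
(2,244 → 1,202/301/741; 12,846 → 6,884/1,722/4,240). Sizes are
seed-independent; membership is randomized per class (stratified).

Training-mode augmentation: bilinear resize to 128×128, uniform random
rotation in [−180°, 180°] with empty corners filled by the image median,
then independent horizontal/vertical flips (p = 0.5 each), then per-channel
normalization (mean 0.5, std 0.5 by default; a pretrained checkpoint's own
constants should be used when fine-tuning from external weights).
Grayscale is replicated to three channels to satisfy the stem. Rotation
range, interpolation and fill were unstated upstream and are package
choices.

## Transfer learning without external weights

No external pretrained checkpoint is assumed. Instead the backbone is
self-pretrained on an auxiliary synthetic shape task — wide vs. narrow
*plain* capsules with no septum or crease cues (300 crops, lr 0.01, step
decay as usual). Donor quality is certified, not assumed: after each
training round (up to 12 epochs, early-stopped at 97% validation accuracy)
the candidate is scored on an independently generated auxiliary holdout,
and training continues — at most three rounds — until the holdout reaches
93%. This matters because the small training-time validation split is
noisy, and an under-converged backbone (in particular one with
uncalibrated batch-norm running statistics) transfers poorly.

Loading a checkpoint replaces every layer except the fully connected head,
which is re-initialized to zero for the target class count. The zero head
is deliberate: the gradient reaching the body through a zero weight matrix
is zero, so the first updates train the head alone and the transferred
features are not disturbed before the head aligns — after which all layers
fine-tune jointly. A topology mismatch raises an error listing the
incompatible layers. The transfer experiment fine-tunes from this
checkpoint vs. random initialization under otherwise identical conditions
(same seed per arm) and records the first epoch at which validation
accuracy reaches 95%.

## Desk-scale study condition

CPU-scale experiments use 200 synthetic images per class with 1–3 cells
each (~800 crops), a width multiplier of 0.25 (channel widths
16/32/64/128, ~0.7 M parameters), 10 epochs, batch 16, lr 0.01. The
larger-than-default learning rate reflects training from scratch on a small
set (a few hundred updates in total); all other hyperparameters keep their
full-scale defaults. The width multiplier is a package addition; full width
remains the default elsewhere.

## Numerical choices and degenerate cases

- Metric conventions: P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R);
  empty denominators yield 0 (P when nothing is predicted positive, R when
  there are no actual positives, F1 when P+R = 0 — consistent with F1 = 0
  whenever TP = 0). Percentages print to four decimals, half-even rounding.
- Prediction ties break to the lower class index.
- Batch normalization: eps 1e−5, running-stat momentum 0.1, biased variance
  in the normalizer, unbiased in the running estimate.
- Weight init: He-normal for convolutions, uniform ±1/√fan_in for the head,
  BN γ = 1, β = 0.
- All randomness flows from one seeded generator per run; pipeline stages
  derive their seeds from the global seed via a seed sequence, so a stage
  can be re-run independently and identical config + seed reproduce
  identical bytes on disk (single-threaded CPU).
- The first convolution skips its input gradient (nothing consumes it).

## Known limitations

- Touching cells become a single crop (no watershed separation); matched to
  the stated extraction procedure and avoided in synthesis by construction.
- Headline accuracies achievable on large curated sets of real Thiosymbion
  micrographs are not reproducible here: no real image set ships with the
  package and full-scale GPU training is out of scope. The desk-scale synthetic condition verifies the
  pipeline's behavior (high test accuracy on separable data; pretrained
  initialization stabilizing no later than random) rather than those exact
  numbers.
- Single split (no cross-validation), matching the original design.
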