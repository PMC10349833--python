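# Methods

## Overview

`dermasp` classifies skin lesions at the *superpixel* level: each image is
reduced to a set of lesion superpixels, each superpixel to six geometric
descriptors, and each descriptor vector to a binary label (nevus = 0,
melanoma = 1).  This note records the models and assumptions behind every
stage, the defaults and why they were chosen, and what the synthetic
evaluation does and does not establish.

## Synthetic data generator

The generator emulates the inputs the pipeline expects from dermoscopy:

- **Skin**: a flat RGB base (default (196, 152, 128)) with i.i.d. Gaussian
  noise, sd 6 intensity units.  This is deliberately *not* a realistic skin
  texture model; see "Limitations".
- **Lesion**: one darker region (default (110, 72, 62)) whose outline is a
  radial function r(θ) = r₀·(1 + a·Σₖ random Fourier terms), orders 2–7
  with the perturbation normalised to unit RMS, then scaled anisotropically
  by the axis ratio and rotated by a uniform random angle.  Defaults:
  r₀ = 75 px in a 256×256 frame (lesions are prominent in dermoscopy
  close-ups); irregularity amplitude a and axis ratio are class-dependent —
  melanoma a = 0.25, axis ratio 0.55; nevus a = 0.05, axis ratio 0.9 —
  so melanoma masks are measurably more eccentric and more irregular.
  The perturbed radius is clipped to [0.2·r₀, min(H,W)/2 − 10] so every
  seed yields a valid single-component in-frame lesion.
- **Hairs**: dark cubic Bézier arcs (default 5 per image, width 3 px) whose
  raster is reproducible from the seed, so tests can score detection
  against the exact drawn pixels.
- **Feature table**: a 6-D Gaussian two-class table whose class means are
  separated by an exact Mahalanobis distance (`separation`), used to test
  the split/normalise/train/score chain independently of image processing.
  The orientation column carries no class shift, mirroring lesions of
  random pose.

All generator outputs are byte-deterministic under their seed.

## Hair removal

Detection thresholds the residual (closing − luminance) at 10 intensity
units, maximised over linear structuring elements of length 11 px at
0°/45°/90°/135°, then dilates by 1 px.  Two refinements proved necessary on
noisy inputs and are exposed as parameters:

- a 3×3 **median prefilter** on the luminance before the closing; without
  it, pixel noise alone pushes the residual over the threshold on the
  majority of hair-free pixels, while hairs (3 px wide) survive the median;
- a **minimum component size** of 50 px on the pre-dilation mask: hairs are
  long curvilinear structures, so short residual fragments (typically at
  the lesion border) are rejected.

Replacement assigns each flagged pixel its nearest unflagged pixel value
(Euclidean distance transform) and then smooths the replaced pixels with a
σ = 1.5 Gaussian; the smoothing removes the seam that the nearest-neighbour
fill otherwise leaves along the hair spine, which a re-run of the detector
would flag.  Pixels outside the mask are never touched.  Grayscale is
Rec. 601 luminance.

## Lesion segmentation

A Boykov–Jolly-style seeded minimum cut on the 4-connected pixel grid.
Seeds are automatic, since lesions are darker than skin: background = the
8-px border frame; foreground = pixels below the 0.1 luminance quantile,
restricted to the central half of the frame, largest connected component.
Data terms are clipped negative log-likelihoods under per-seed-class
Gaussian luminance models (sd floored at 1 to tolerate flat seed regions);
smoothness terms are λ·exp(−(Iᵢ−Iⱼ)²/2σ²)/dist with λ = 50, σ = 10.
Capacities are quantised by a factor of 50 to integers for the max-flow
solver (`scipy.sparse.csgraph.maximum_flow`), so the minimised energy is
exact on that quantised scale — the test suite verifies optimality against
exhaustive enumeration on seeded miniatures at that same quantisation.
Post-processing keeps the component(s) containing foreground seeds and
fills holes, yielding the single filled lesion region downstream stages
assume.

## iSLIC

SLIC is implemented in-package following the canonical formulation: grid
initialisation with nₓ ≈ √(n·W/H) columns, centre perturbation to the
lowest-gradient pixel in a 3×3 window, assignment within 2S×2S windows by
D² = d_lab² + (d_xy/S)²·m² (m = 10), ten iterations, then connectivity
enforcement: every label becomes one 4-connected component and fragments
smaller than (HW/n)/4 are absorbed by their largest adjacent region,
smallest-first, with labels compacted to 1..L.  Background elimination
keeps a superpixel when ≥ 50% of its pixels fall inside the lesion mask
(majority rule; in practice SLIC snaps to the black/lesion contrast so
almost every superpixel is entirely inside or outside).  SLIC runs on the
full-frame masked image, not a crop; with n = 100 on 256×256 frames this
yields ≈ 14–24 kept superpixels per lesion.

## Dataset assembly and classifiers

Records are split at the superpixel-record level (stratified by class,
round(0.7·n) per class to training); superpixels of one image can land on
both sides of the split, which mirrors how such record-level protocols are
usually run but is *not* leakage-safe — image-level grouping is available
by filtering on `image_id` before splitting.  Normalisation is z-score with
population (ddof = 0) moments fitted on the training partition only, and is
exactly invertible from the stored parameters.

The six classical learners carry fixed hyperparameters (RF: 100 trees,
entropy; SVM: linear kernel, one-vs-one; AdaBoost: 100 stumps, SAMME,
random_state 40; KNN: k = 1, kd-tree, Euclidean; DT: entropy, depth ≤ 100;
GNB: var_smoothing 1e−9); anything unlisted uses scikit-learn defaults.
The three networks run on the in-package numpy layer framework:

- **PRNN** — dense 10(tanh) → 1(sigmoid), cross-entropy, trained full-batch
  with plain gradient descent at rate 0.01 for 100 epochs.  This
  approximates scaled-conjugate-gradient pattern-recognition training with
  a generic full-batch optimiser of the same architecture and loss; exact
  optimiser reproduction is a non-goal.
- **FNN** — dense 10–8–6 (tanh) → 1(sigmoid), Adam at 0.001, batch 32,
  100 epochs, binary cross-entropy.
- **1D-CNN** — input (6, 1): conv(64, k=2, relu) → dropout 0.2 →
  conv(32, k=1, relu) → maxpool(1) → flatten → dense(32, relu) →
  dense(1, sigmoid); Adam at 0.001, batch 32, 100 epochs (7 457 parameters,
  matched against layer-shape arithmetic in the tests).  Batch size was
  unstated upstream; 32 is the conventional default.

Networks threshold the sigmoid at 0.5.  `train_model` fits on the full
training partition and records the mean fivefold cross-validation accuracy
(balanced folds, sizes within one record) as an overfitting diagnostic.
All stochastic learners are seeded; identical data + seed reproduces
identical predictions.

## Metrics

Accuracy, precision, recall, F1 and MCC from TP/TN/FP/FN with melanoma as
the positive class throughout.  A zero denominator reports that metric as
0.0 with an `undefined` flag instead of raising, so batch sweeps never
abort; the flag is serialised in the metrics JSON.

## Numerical choices and degenerate inputs

- Second moments carry the +1/12 diagonal correction, so a single pixel has
  a well-defined ellipse (major axis 4/√12) and eccentricity stays < 1 for
  thin regions.
- Orientation is ½·atan2(2μ₁₁, μ₂₀−μ₀₂) in the y-up frame, degrees in
  (−90°, 90°]; it is compared modulo 180° in tests since a symmetric region
  has no preferred direction.
- Perimeter is the closed Moore-boundary chain with steps 1/√2 — *not* the
  corner-corrected estimator some toolboxes use; a 10×10 square scores 36,
  an isolated pixel 0.
- Convex area counts pixel centres inside the hull of the region's pixel
  centres; collinear regions fall back to the pixel count.
- Multi-component region masks (possible after aggressive mask
  intersection) are reduced to their largest component before feature
  extraction.
- Graph-cut hard seeds get capacity 10⁹, far above any feasible cut under
  the clipped data terms, so seed compliance is structural.

## Problem sizes

The bundled study uses 60 synthetic images (30 per class) at n = 100
superpixels, which yields ≈ 1 100 records; classification results are
averaged over three split/training seeds on that fixed cohort.
Segmentation quality is probed on 10 images and hair removal on 5.  These
sizes keep the full suite and the acceptance script comfortably
reproducible on a single CPU while leaving the statistics stable to within
a few hundredths.

## What the synthetic study shows — and does not

Passing tests establish that every stage honours its contract: hairs are
detected and removed, the graph cut recovers the true lesion mask
(IoU ≈ 1.0 at the default contrast), superpixels partition the frame and
the background ones are eliminated, features match independent brute-force
oracles, and the training protocol is leakage-free in its normalisation and
reproducible end to end.

They do **not** show that single-superpixel geometry suffices to diagnose
the synthetic lesions.  With the generator's design, interior lesion
superpixels are near-regular SLIC tiles that are statistically
exchangeable between classes, and the low-order border perturbation varies
on wavelengths (≈ 67–236 px) well above the superpixel diameter (≈ 26 px),
so the class signal reaching an individual superpixel is weak: per-record
accuracy plateaus around 0.6–0.7 for every classifier even with more
training images, while the same images are perfectly separable from
whole-lesion features.  On real dermoscopy data, texture- and
colour-driven variation gives each image a distinctive superpixel
signature, and record-level splitting lets classifiers exploit
correlations between same-image superpixels — an effect the flat-noise
generator deliberately does not emulate.  High per-superpixel accuracies
reported on real collections should therefore be read with the
record-level split in mind, and the leakage-safe image-level split is the
fairer benchmark.

## Known limitations

- No realistic skin texture, ruler marks, gel bubbles or illumination
  gradients; hair is the only artifact modelled.
- Single-lesion images only; the graph cut assumes the lesion is darker
  than the surrounding skin.
- Bit-compatibility with MATLAB toolbox regionprops/graph-cut outputs is a
  non-goal; conventions are documented and oracle-tested instead.
- The public-dataset adapters enumerate files and map labels; they do not
  validate image content or download anything.
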