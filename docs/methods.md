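# Methods

## The workflow being modelled

Adaptive MR-Linac prostate radiotherapy produces one T2-weighted 3D MR image
per treatment fraction. The package trains a segmentation model on the
single labelled image of fraction 1 of a patient and applies it to that
patient's fractions 2+. Everything is patient-specific: the model, the crop,
the intensity window. The package's scope is the contouring workflow and its
geometric evaluation; it does not model MR physics, treatment planning or
dose.

## Network and training

The segmenter is a conventional 2D U-net applied slice-by-slice along the
transversal (feet-head) axis:

* `depth` pooling levels (default 4), `base_filters` channels at the top
  (default 32) doubling per level; two 3×3 convolutions + SeLU per level;
  2×2 max-pool down, 2×2 transposed convolution up, skip concatenation;
  1×1 convolution + softmax into 4 classes. LeCun-normal initialisation
  (the matching choice for SeLU's self-normalising property), alpha dropout
  (default rate 0.4) at the deepest level only.
* Training samples random `patch_size`² in-plane patches (default 128²,
  uniform over slices and valid corners) from the cropped, windowed training
  volume; batch size 4; Adam with learning rate 1e-4, fixed (no schedule, no
  early stopping); total 1000 epochs with a checkpoint every 100.
* An "epoch" is not defined by the source data (a single volume sampled as a
  patch stream has no natural epoch); here one epoch consumes
  `patches_per_epoch` patches (default 64, i.e. 64 000 patches over a full
  run). This is a package definition, configurable.
* Loss is the focal loss −(1−p_t)^γ log p_t averaged over pixels, γ = 2 by
  default, with no per-class α weights.
* Augmentation per patch, in order: a shared smooth elastic deformation
  (control grid spacing 32 px, control displacement sd 2 px; linear
  interpolation for the image, nearest-neighbour for labels), additive
  Gaussian noise (sd uniform in [0, 0.05] on the [0, 1] intensity scale),
  and a contrast-gamma transform (exponent uniform in [0.8, 1.25]). The
  magnitudes are deliberately small; they are calibration choices exposed in
  `AugmentConfig`.

The architecture internals (exact depth, filter counts, upsampling type)
are conventional U-net choices and fully configurable; nothing downstream
depends on them beyond the 2^depth divisibility constraint.

### The numpy engine

No GPU framework is used: convolutions, pooling, transposed convolutions,
SeLU/alpha-dropout and Adam are implemented directly on numpy in
channels-last layout, with convolutions expressed as sums of shifted
channel-matrix products (BLAS-backed). Every primitive and the composed
network are verified against central finite differences in float64 in the
test suite. All randomness flows from seeded `numpy.random.Generator`
objects, so training is reproducible bit-for-bit on a given platform.

## Preprocessing

* **Crop.** The smallest box containing all labelled voxels, expanded per
  axis to at least min(256, 256, 128, grid extent), centered on the
  bounding box and shifted minimally to stay in-grid. The training-time
  crop is stored in every checkpoint and reused at inference — a test
  fraction has no labels to crop to, and the MR-Linac geometry is fixed
  between fractions. This reuse is a package decision, not a property of
  the clinical system.
* **Normalization.** Clip to the [1st, 99th] percentile window of the
  (cropped) training volume, map affinely to [0, 1]; the same window is
  applied to test fractions. Percentile clipping tames bright outliers
  (gas pockets); the scheme is invariant to positive affine rescalings of
  the scanner intensity scale. Constant volumes map to zeros.

## Inference

Each ensemble member (the `ensemble_size` = 3 highest-epoch checkpoints)
runs on full cropped slices — the network is fully convolutional, so no
patch tiling and no seam artifacts; sides are reflect-padded to the next
multiple of 2^depth. Member probability maps are averaged (soft voting) and
the argmax taken, ties broken toward the lowest class index (background
wins — conservative). Outside the crop everything is background.
Postprocessing keeps, independently per foreground class, only the largest
26-connected 3D component ("coherent structure" is read volumetrically, not
slice-wise); ties break toward the component containing the
lexicographically smallest voxel.

## Evaluation

* **Dice** 2|A∩B|/(|A|+|B|); both-empty pairs score 1.0 (perfect agreement
  on absence).
* **APL** is computed slice-wise in 2D (contours are drawn and corrected
  per transversal slice in the workflow the metric models). A contour pixel
  is a foreground pixel 4-adjacent to background or to the grid edge. On
  each slice, the *generated* contour's pixels whose distance to the
  nearest *reference* contour pixel exceeds the tolerance are counted;
  slices with an empty reference contribute the whole generated contour.
  The default tolerance is 1 pixel in the **Chebyshev** metric (so "within
  tolerance" means an 8-neighbourhood hit), ignoring voxel anisotropy;
  Euclidean distance is available via `ToleranceSpec(metric="euclidean")`.
  APL is directional; part of the literature counts reference pixels not
  covered by the generated contour instead.
  `ToleranceSpec(direction="ref_vs_auto")` flips the direction; the default
  tests generated against reference.
* **Wilcoxon signed rank**, two-sided, pairs aligned on
  (patient, fraction, structure). Zero differences are dropped before
  ranking (classic Wilcoxon, not Pratt); ties get midranks. For n ≤ 25
  non-zero pairs the exact null distribution is computed by convolution
  over rank sums, with the two-sided p defined symmetrically as
  P(|W − μ| ≥ |w_obs − μ|) — this stays well-defined under midranks. Above
  n = 25 a normal approximation with tie correction and 0.5 continuity
  correction is used. Comparing two identical reports is reported as a
  "no difference" entry rather than an error.

## The synthetic phantom

The phantom emulates the *statistical structure* of daily pelvic MR, not
its appearance:

* **Geometry.** Analytic shapes on a default 96×96×32 grid at
  0.86 × 0.86 × 1 mm: CTV ellipsoid (semi-axes 11, 9, 7.5 voxels), bladder
  ellipsoid superior-anterior of it (15, 13, 8), rectum as a curved tube
  (radius 5) running the full feet-head extent posterior to the CTV.
  Overlaps resolve by priority CTV > rectum > bladder (target integrity
  first). After cropping, ~96 % of voxels are background, inside the
  0.85–0.97 band that brackets the class imbalance of cropped clinical
  data.
* **Interfractional variation.** Per fraction ≥ 2, each organ's volume is
  scaled isotropically about its centroid by a ratio drawn within a
  per-organ band (defaults ±5 % CTV, ±40 % bladder, ±25 % rectum — small
  target changes, large filling changes; the rectum scales its
  cross-sectional radius since its centerline spans the grid), then a
  shared smooth displacement field is applied (trilinear from a control
  grid, default spacing 16 voxels, per-voxel magnitude ≤ 1.5 voxels; the
  magnitude must stay below half the control spacing, keeping the field
  invertible in practice). Ratios are drawn from the inner 85 % of the
  band and the final voxel counts are checked against the full band, so
  voxelization and deformation can never push an organ outside its
  configured range; draws that fail the check (or push an organ to the
  grid boundary) are rejected and resampled with a bounded retry count.
* **Appearance.** Piecewise-constant T2-like means on an arbitrary
  [0, 1000] scale (background 150, rectum 300, CTV 450, bladder 900),
  multiplied by a low-frequency bias field (amplitude 0.10) and degraded
  with Gaussian noise (sd 25). Optional "bright gas pockets" render a
  random feet-head segment of the rectum at an intensity above the bladder
  mean; by default pockets are off, and when enabled they are excluded
  from the training fraction so they model contrast *unseen* at training
  time — the clinically observed failure mode. The acceptance suite checks
  that such pockets strictly reduce rectum Dice.
* **What it does not model.** MR physics (no k-space or sequence
  simulation), inter-patient anatomical diversity, observer variability in
  the reference contours, and intensity non-reproducibility between
  scanners. Passing tests on the phantom therefore demonstrate the
  *mechanics* of the workflow (training, ensembling, metrics) and the
  direction of its failure modes, not clinical-level accuracy: the phantom
  task is much easier than clinical segmentation, so its Dice values are
  optimistic.

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` run a down-scaled study: the
default 96×96×32 phantom with mild variation (≤5 % CTV, ≤20 % bladder,
≤10 % rectum), a depth-3 / 8-filter U-net on 64² patches, 150 epochs with a
checkpoint every 50 and the 3-member ensemble. These sizes were chosen so a
full training runs in a few CPU-minutes while preserving every structural
element of the full recipe (patch training, focal loss, checkpointing,
ensembling, postprocessing). Unit tests use a still smaller 48×48×16
phantom.

## Known limitations

* 2D slice-wise processing cannot use out-of-plane context; the cranial
  extent of tubular organs is the first casualty (visible in the rectum
  scores).
* One shared model for three structures of very different sizes leaves the
  CTV exposed to residual class imbalance even with focal loss.
* The training crop is reused at inference; large couch or patient shifts
  between fractions would break this assumption and are not modelled.
* The engine is CPU-only; full-scale training (1000 epochs, 128² patches,
  depth 4, base 32) is supported but slow — hours rather than minutes.
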