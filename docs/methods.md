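# Methods

This note records the models, defaults and numerical choices behind
`reeffusion`, and what the synthetic benchmarks do and do not demonstrate.

## Data model

A *registered pair* holds a reflectance image (H × W × 3, RGB) and a
fluorescence image (H × W × 2) on the same pixel grid.  The fluorescence
camera's blue channel overlaps the blue excitation light and is discarded at
the type level, so a pair carries five informative channels in the fixed
stack order `R_ref, G_ref, B_ref, R_flr, G_flr`.  Intensities are normalized
to [0, 1] on read, whatever the source bit depth, so downstream processing is
file-format independent.  Pixel coordinates are 0-based `(row, col)` with the
point at the pixel center.

Annotations are single-pixel expert labels from a fixed 10-category set; the
six hard-coral categories (five genera plus other-hard-coral) collapse to
`coral` in the binary coral-vs-other task, everything else — including the
hydrozoan *Millepora* and `unknown` — to `other`.  A `macroalgae` label may
appear in annotation exports but is dropped on read (it is vanishingly rare
in the data regime this package targets); any other unknown label is a hard
error, as is an out-of-bounds point.  The CSV schema (`image,row,col,label`,
comma-separated, header required) is a minimal form of a CoralNet-style point
export.

## Registration

Cameras were swapped on a fixed frame, so residual misalignment is modelled
as a global affine map from the fluorescence frame to the reflectance frame
(annotations live on reflectance images, fixing the warp direction).  With
n ≥ 3 non-collinear correspondences the six parameters minimize
Σ‖x_ref − (A x_flr + t)‖²; the solver is ordinary least squares on the
stacked linear system, and the fit RMSE is reported.  Collinear or
insufficient landmarks raise a degenerate-geometry error rather than
returning an ill-posed warp.

Resampling is bilinear.  Output pixels that map outside the source image are
zero-filled and recorded in a validity mask; annotated points that land on
masked pixels are skipped with a warning in every consumer (patch extraction,
intensity features).  Warping with the identity is bit-exact, and integer
translations shift pixel content without interpolation blur — both are
regression-tested.

## Patches and augmentation

Each annotation yields a centered 128 × 128 crop, reflection-padded at image
borders (zero padding would inject artificial black texture at frame edges).
Crops are resized to 32 × 32 by plain bilinear interpolation with half-pixel
center alignment and no smoothing prefilter; this keeps constants constant,
affine intensity ramps affine, and all outputs inside the input range.
Training patches are expanded to the full 8-element dihedral orbit
(rotations by right angles × optional mirroring, pixel-exact); evaluation
patches are never augmented, and no test-time score averaging is performed.
The rotation convention is counter-clockwise with mirroring about the
vertical axis — any consistent convention yields the same orbit.  Crop and
resize order follows the preprocessing pipeline (crop → resize → augment);
for right-angle operations the order of resize and augmentation commutes.

## Patch networks

All three networks (`f_ref`, `f_flr`, `f_five`) share one architecture for
32 × 32 inputs: three blocks of 5 × 5 stride-1 'same' convolution, 3 × 3
stride-2 max pooling, and ReLU, followed by a linear 10-way head.  The
reference filter widths are 32/32/64; a *reduced* configuration (8/8/16
filters, 3 epochs) with identical depth and layer types is the default for
CPU-scale experiments and is what the synthetic benchmark and acceptance runs
use.  Training minimizes softmax cross-entropy with SGD, momentum 0.9, weight
decay 1e-4, batch size 128, and a step learning-rate decay (×0.1 at 75% of
epochs); initialization is He-scaled Gaussian.  Per-channel means are
computed on the training set and subtracted identically at train and test
time.  Every class of the label set must be present in training data;
channel-count mismatches are errors.

The implementation is pure numpy: convolutions run as im2col matrix products
in a channels-first (C, N, H, W) layout chosen to avoid transposes on a
single core, the first conv layer skips its input gradient, and the dihedral
training augmentation is expanded batch-by-batch inside the optimizer (the
tensors seen by SGD are identical to pre-augmenting at one eighth the
memory).  All randomness (init, shuffling) flows from the spec seed, making
training bit-reproducible on a given machine.

Scores passed downstream are pre-softmax logits (the fusion stage
standardizes them anyway); softmax probabilities are available via
`score_mode="softmax"`.  Classification is the argmax over the 10 scores,
with ties broken toward the lowest canonical label index.

## Score fusion

For every annotated point (un-augmented patch, one vector per point) the two
per-modality score vectors are concatenated to a 20-dimensional joint score,
reflectance half first.  Because logits from independently trained networks
live on incommensurate scales, each joint dimension is standardized to zero
mean and unit variance using training-set statistics only — leakage is
asserted by recomputation in the tests.  The second-stage classifier is a
linear one-vs-rest SVM; its constant C is selected from {1e-3 … 1e3} by
5-fold stratified cross-validation on the training set.  The hinge loss is
scaled per-sample (C/n), which makes the fitted decision function invariant
to duplicating the training data.

## Intensity baseline

The baseline asks how far single-pixel color gets without texture: for any
subset of the five channels, the raw intensities at annotated pixels feed an
RBF-kernel SVM with (C, γ) chosen by 5-fold grid cross-validation
(exponential grids, C ∈ 2^-5 … 2^15, γ ∈ 2^-15 … 2^3, step 2^4 by default).
Intensities are used raw in [0, 1] — no per-image normalization.  Reported
subsets mirror the standard analysis: each single channel, the reflectance
triplet, the fluorescence pair, and all five; accuracies are aggregated with
exactly the same per-image machinery as the network evaluation (shared code
path), for both the 10-class and the coral-vs-other task.

## Evaluation protocol

Per-image accuracy is the fraction of points classified in agreement with
the expert; the summary is mean ± SE over test images with
SE = SD/√n_images.  Confusion matrices are row-normalized with per-row truth
counts retained (count-weighted entries reconstruct the totals); empty
classes keep zero rows and count 0.  Precision–recall curves sweep a
one-vs-rest threshold on each class's score; classes absent from the truth
are marked undefined.

The paired comparison is a Wilcoxon signed-rank test on per-image accuracy
differences, one-sided by default (the question is whether classifier A is
*better*); two-sided is available.  Zero differences are discarded (classic
Wilcoxon rather than Pratt's variant), tied absolute differences get average
ranks, and the null distribution of W⁺ is computed exactly by dynamic
programming over the rank generating polynomial for up to 25 nonzero
differences — this handles half-integer average ranks exactly, which
off-the-shelf exact implementations do not — with a tie-corrected,
continuity-corrected normal approximation beyond.  All differences zero
yields p = 1 with a degenerate flag.  Error-rate reduction between
accuracies a_A, a_B (percent) is reported as the absolute error difference
and as a percentage of A's error rate; the relative figure is NaN-flagged
when A has zero error.

No multiple-testing correction is applied across pairwise comparisons,
matching the protocol the package reproduces.

## Synthetic surveys

The generator emulates the *data regime* of a paired-camera nighttime reef
survey, not its optics.  A scene is a nearest-site tessellation of seeded
random sites (default 25 regions on a 256 × 256 canvas), each region drawing
a class from a prior; classes render as a mean reflectance color and a mean
fluorescence emission plus shared band-limited texture (smoothed white noise,
per-class amplitude, default 0.03) and i.i.d. Gaussian pixel noise (default
SD 0.02).  A random similarity-like affine (rotation ≤ 1.5°, scale ± 2%,
translation ≤ 4 px about the image center by default) misregisters the
fluorescence frame, and at least four exact landmark correspondences are
emitted, so the registration module can recover the truth to ≤ 1e-6.  200
uniform point annotations per image are labelled from the ground-truth
region map.  All randomness flows from a single seed.

`complementary_benchmark` (40 train / 20 test images) makes the five coral
genera share one fluorescence emission while differing in reflectance color,
and the five remaining classes share one reflectance color while differing
in emission.  The Bayes rule of the generating model is then near-perfect on
the joint channels but near 60% for either modality alone, so a correct
fusion stage must dominate both single-modality networks — the structural
analogue of the field finding this package operationalizes.
`single_channel_benchmark` puts the only class signal in the fluorescence
green channel (a 10-level emission ladder), reproducing the situation where
one spectral band carries the discriminative color information.

What passing these benchmarks shows: the pipeline's registration, patching,
training, fusion and statistics interact correctly, and fusion extracts
complementary information when it exists.  What it does not show: real coral
texture, within-class appearance variability, water-column color
degradation, fluorescence polymorphism, or class imbalance as found in field
data — absolute accuracies on synthetic scenes say nothing quantitative
about field accuracy.

## Problem sizes and determinism

Desk-scale defaults were chosen so a full benchmark experiment (60 scenes,
12,000 points, three networks plus fusion) completes in roughly a quarter
hour on one CPU core: reduced filter widths 8/8/16, 3 epochs, 256 × 256
scenes.  The acceptance script runs the same sizes.  Every experiment result
embeds its config digest and seed, and rerunning with the same configuration
reproduces identical JSON output.

## Known limitations

- The networks are CPU-bound numpy; the full 32/32/64 configuration at field
  scale (28,400 × 8 training patches, 60 epochs) is supported but slow — it
  is the configuration to use when reproducing field-scale results on real
  data.
- The registration model is strictly affine; lens distortion or local
  parallax is out of scope.
- The generator's texture is isotropic band-limited noise; it cannot test
  texture-specific failure modes.
- Fusion is score-level only (plus the five-channel pixel-level variant);
  no probabilistic calibration of scores is attempted.
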