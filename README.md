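# reeffusion

Automated point annotation of benthic (sea-floor) survey images from **two
imaging modalities**: conventional strobed reflectance photographs (RGB) and
wide-band fluorescence photographs captured with a modified consumer camera
whose usable channels are red (chlorophyll-*a* emission) and green (GFP-band
emission).  The package is aimed at coral-reef ecologists and computer-vision
practitioners who estimate percent cover from expert point annotations and
want to know how much fluorescence adds to an automated annotator.

## What it does

A survey contributes image *pairs*.  Each pair is brought into a common pixel
frame by a **landmark affine registration**: hand-clicked (or synthetic)
correspondences `(x_flr, x_ref)` determine the least-squares affine warp
`x_ref = A x_flr + t`, and the fluorescence image is bilinearly resampled onto
the reflectance grid.  Expert annotations are points: 200 random pixel
locations per image, each labelled with one of ten benthic categories (five
dominant hard-coral genera — *Faviidae*, *Stylophora*, *Platygyra*,
*Acropora*, *Pocillopora* — plus other-hard-coral, *Millepora*,
bare-substrate, other-invertebrates, and unknown).

Classification is patch-based.  Around every annotated point a centered
128 × 128 patch is cropped, bilinearly resized to 32 × 32, and (for training
only) expanded to its 8-element dihedral orbit (rotations by 0°/90°/180°/270°,
each optionally mirrored).  Three convolutional networks share the classic
cifar10 shape — three rounds of 5 × 5 convolution, 3 × 3 stride-2 max pooling
and rectification, then a linear 10-way head:

- `f_ref : q(R,G,B) -> s` on reflectance patches,
- `f_flr : q(R,G) -> s` on fluorescence patches,
- `f_five : q(R,G,B,R_flr,G_flr) -> s` on the stacked five-channel patches,

each emitting a score vector `s` over the 10 categories; a patch is assigned
`y = argmax_i s_i`.  The headline classifier `f_joint` is **late fusion**: the
two per-modality score vectors are concatenated to a 20-dimensional joint
score, standardized with training-set statistics, and mapped to a label by a
linear SVM whose regularization constant is cross-validated on the training
set.

Evaluation follows the paired per-image protocol: accuracy `a(i)` is the
fraction of correctly classified points of test image `i`, summarized as
mean ± SE over images; classifiers A and B are compared by a one-sided
Wilcoxon signed-rank test on `d(i) = a_A(i) − a_B(i)` (exact null
distribution up to 25 nonzero differences, tie-corrected normal approximation
beyond).  Confusion matrices are row-normalized (diagonal = recall),
one-vs-rest precision–recall curves sweep each class's score threshold, and
error-rate-reduction arithmetic converts accuracy gains into the fraction of
annotation errors corrected.  An **intensity-only baseline** (RBF-kernel SVM
on single-pixel intensities of any channel subset) measures how much of the
signal is pure color before texture enters.

Because the original field data require a separate download, the package
ships a first-class **synthetic survey generator**: nearest-site region
tessellations with class-conditional reflectance color, fluorescence
emission, band-limited texture, noise and controllable affine
misregistration.  The `complementary_benchmark` preset makes five classes
separable only by reflectance and five only by fluorescence, so score fusion
must beat either single modality — the structural analogue of the field
result it emulates.

## Worked example

```python
from reeffusion import synthdata, pipeline

bench = synthdata.complementary_benchmark(seed=1, n_train=8, n_test=4)
pairs = pipeline.register_benchmark(bench.train + bench.test)
config = pipeline.ExperimentConfig(
    seed=1,
    train_ids=tuple(p.pair_id for p in bench.train),
    test_ids=tuple(p.pair_id for p in bench.test),
    network_overrides={"epochs": 2},
)
result = pipeline.run_experiment(
    pairs, bench.train_annotations + bench.test_annotations, config
)
for name, rep in result.reports.items():
    print(f"f_{name}: {100 * rep.mean_accuracy:.1f} +/- {100 * rep.se_accuracy:.1f} %")
print("joint vs ref: p =", result.comparisons["joint_vs_ref"].p_value)
```

At this miniature scale (8 training images, 2 epochs) the run prints:

```
f_ref: 55.4 +/- 2.3 %
f_flr: 41.3 +/- 5.4 %
f_five: 74.5 +/- 2.6 %
f_joint: 80.1 +/- 1.2 %
joint vs ref: p = 0.0625
```

Each single-modality network is capped by construction (half the classes are
invisible to it), both five-channel and fused classifiers recover the
complementary information, and the signed-rank p-value is the smallest
attainable with only 4 test images (1/2⁴).  The full-size benchmark (40/20
images) gives the fused classifier a double-digit accuracy lead with
p < 0.001.

The same experiment is scriptable from the shell:

```bash
reeffusion run-all --preset complementary --out results/ --seed 0
reeffusion simulate --preset default --out data/ --seed 1 --n-images 6
reeffusion register --pairs data/ --points data/correspondences.csv --out registered/
```

## Layout

- `src/reeffusion/datamodel.py` — label set, registered pairs, annotation CSV I/O
- `src/reeffusion/registration.py` — landmark affine fit + bilinear warp
- `src/reeffusion/patching.py` — crop / resize / dihedral augmentation
- `src/reeffusion/cnn.py` — the patch networks (numpy, im2col + SGD)
- `src/reeffusion/fusion.py` — 20-dimensional score fusion (linear SVM)
- `src/reeffusion/intensity.py` — RBF-SVM intensity baseline per channel subset
- `src/reeffusion/evaluation.py` — per-image accuracy, confusion, PR, Wilcoxon
- `src/reeffusion/synthdata.py` — synthetic survey generator + benchmarks
- `src/reeffusion/pipeline.py`, `cli.py` — orchestration and `reeffusion` CLI

See `docs/methods.md` for the modelling choices, defaults and limitations.
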