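# Methods

## Problem and scope

The package estimates three growth traits of greenhouse lettuce — leaf fresh
weight (LFW, g), leaf dry weight (LDW, g) and total one-sided leaf area (LA,
cm²) — from nadir images, and compares three families of estimators under one
evaluation protocol: a multi-output convolutional regressor on raw RGB,
shallow regressors (SVR, random forest) on handcrafted color/texture/shape
features, and univariate linear models on depth-derived structural traits.
Everything runs on synthetic scenes with exact ground truth; no external data
is downloaded or required.

## Synthetic scene generator

A scene is a rosette of `n` overlapping leaves on a dark tray viewed from a
sensor at `sensor_height` (default 78 cm) with scale `px_per_cm` (default 10)
on a square canvas (default 256 px).

**Leaf geometry.** Each leaf is a lobed ellipse in leaf-local polar
coordinates, r(φ) = r_ell(a,b,φ)·(1 + λ·cos(kφ + φ₀)). Its true one-sided
area is computed *before* rasterization by trapezoid quadrature of ½∫r²dφ
(error ≲ 10⁻⁴ relative at 180 boundary samples); for an unlobed ellipse this
reduces to πab exactly. Leaves are placed by golden-angle phyllotaxis,
rasterized as polygons and composited through a z-buffer, so the renderer
knows both the total modelled leaf area (including occluded parts) and the
visible projected area. Leaf count and mean leaf size rise with the weekly
session index (1..7): expected count interpolates the cultivar's
`leaf_count_range`, mean semi-major axis is 0.9 + 0.85·stage cm, giving LA of
order 10¹ cm² at transplanting and 10³ cm² at harvest.

**Cultivars.** Two flat-leaf cultivars and one curled-leaf cultivar
(`curl_amplitude` = 1). Curling has two effects: a wavier, higher-frequency
leaf margin, and a radial foreshortening of the rasterized footprint by
1/(1 + 0.22·curl) while the true (curved-surface) area is kept — so curled
plants hide strictly more leaf area per projected pixel, which is what
degrades top-view estimation for curly cultivars in practice.

**Traits.** LA is the exact sum of per-leaf areas. LFW = α·LA^β·e^ε with
α = 0.035 g·cm^(−2β), β = 1.1, ε ~ N(0, 0.08²); LDW = dmf·LFW·e^ε′ with
cultivar dry-matter fractions around 0.05 and the same scatter. These values
put a stage-7 plant near 190 g fresh weight, the right order for mature
greenhouse lettuce, and make the allometric exponent recoverable by
regression (asserted in tests).

**Depth.** The canopy is a fairly flat dome: leaf i of n sits at
h_max·(0.78 + 0.22·(i+1)/n) with h_max = 2.8 + 0.95·stage cm (≈3.8 cm at
transplanting, ≈9.5 cm at harvest), with a mild radial taper and, for curled
leaves, a ripple. Depth is written as 16-bit PNG in mm (sensor-to-surface);
plant pixels are strictly nearer than the ground plane. Heights are in cm
everywhere else; the mm↔cm conversion happens at exactly one point
(`structural_features`).

**What the generator does not emulate:** photorealistic texture, specular
highlights, soil/moisture variation, neighbouring plants, sensor noise floors
and depth shadows of real RGB-D cameras. Passing tests therefore demonstrate
correctness of the estimators and protocol, not field-ready accuracy on real
greenhouse imagery.

## Preprocessing, split, augmentation

Images are cropped to a square (auto mode: the plant bounding box from an
excess-green map plus a 5% margin, clamped inside the frame) and resized
bilinearly. The train/test split is 8:2 with round-half-up at the global
level, reconciled per (cultivar, session) stratum by largest remainder so
every stratum of size ≥ 2 appears on both sides; 20% of the training images
become the validation set. Augmentation enlarges the training set exactly
26-fold: the six lossless geometric variants (identity, three right-angle
rotations, two flips) plus four HSV value-channel scalings (0.8, 0.9, 1.1,
1.2) applied to each of the five non-identity geometric variants
(6 + 5·4 = 26). Several factorizations of the same transform lists are
arithmetically possible (6·5 = 30, 6 + 4 = 10); the 6 + 5·4 rule is the one
consistent with a 26× enlargement using exactly those transforms, and the
factor is always derived from the rule, never hard-coded. Augmentation is
never applied to validation or test images.

## CNN

Reference architecture: conv(5×5)×5 with channels (32, 64, 128, 216, 512),
zero padding (1 px) on conv2 and conv3 only, 2×2 stride-2 average pooling
after conv1–4, ReLU after every convolution, dropout 0.5 on the flattened
512-vector, dense layer to 3 outputs. The side sequence
128→124→62→60→30→28→14→10→5→1 is the unique integer-sided plan with four
pools and padding on exactly two layers; `layer_shape_plan` machine-checks
any configuration and rejects those whose pooled sides would be fractional.

Choices the architecture description leaves open, fixed here: ReLU
activations; mean-squared-error loss over the three outputs with per-trait
standardization of targets (so grams and cm² do not dominate each other);
dropout placed on the flattened features; He fan-in weight initialization;
SGD momentum 0.9 (0 gives plain SGD) with global gradient-norm clipping
(default 5, disable with None) — without it, an unlucky initialization can
blow up in the first epochs, silence every ReLU and leave the network
predicting the target mean. Training keeps the weights with the
best validation loss. The schedule lr(e) = lr₀·0.1^⌊e/20⌋ is exact and
tested. Inputs are scaled to [0,1]; predictions are de-standardized and
negatives clamped to zero with a logged count.

The network is pure NumPy: im2col convolution lowered to single BLAS matmuls,
reshape-based pooling, manual backpropagation (verified against numerical
gradients in development). The first convolution skips its input-gradient
computation, which nothing consumes. Memory scales with
batch·im2col(conv1) ≈ 0.5 GB at batch 128 full width; the scaled benchmark
below stays far under that.

## Benchmark configuration

The trait-recovery benchmark (also run by `scripts/acceptance.py`) uses 300
scenes (100 per cultivar, sessions balanced), split 8:2, and a width-reduced
network — channels (8, 16, 32, 54, 128), identical topology — trained 40
epochs at batch 32 with lr₀ = 0.01 (step schedule unchanged). The narrower
width and larger lr₀ suit the smaller batch and dataset; one fit takes a few
minutes on a single core. The reference width and schedule remain the
package defaults. Handcrafted features are extracted at native resolution on
the same split (fit on train+validation, scored on test); depth models fit
H/PA/V by OLS on the same ids. Expected behaviour, asserted in tests:
test R² ≥ 0.75 for all three traits for the CNN, the projected-area feature
top-ranked by the Pearson screen for every trait; the orderings
CNN ≥ {SVR, RF} and {LR-V, LR-PA} > LR-H are data-dependent and are checked
as warnings, not failures.

## Handcrafted features

The 15 color components are the three channels of RGB, HSV, CIEL\*a\*b\*,
YCbCr (named Y, Cr, Cb) and HSI (hue/saturation/intensity with the standard
arccos hue and S = 1 − min/I — distinct from HSV). Color statistics use
masked pixels only. GLCMs are computed per component on the masked region:
16 quantization levels spanning the masked min–max, displacement 1,
symmetric counting, statistics averaged over the four standard directions
(0°, 45°, 90°, 135°). Conventions: energy is the angular second moment Σp²,
homogeneity Σp/(1+|i−j|), contrast Σp(i−j)², correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) with the degenerate single-level case defined as 1.0
so vectors stay finite. Every statistic is tested against a brute-force
pair-enumeration oracle. Shape features are mask pixel count and boundary
perimeter. Whether real pipelines mask the GLCM or use the full crop varies;
masking is used here so the features describe the plant, not the tray.

## Segmentation

RGB: Otsu split of the a\* channel (vegetation strongly negative), hole
filling, largest connected component; a greenness-margin guard (foreground
must be ≥ 8 a\* units greener than background) turns vegetation-free images
into an explicit error instead of a garbage mask. Depth: SLIC superpixels on
the normalized depth map (the superpixel backend is pluggable), seed = the
superpixel whose centroid is nearest the image centre, then
region growing over the adjacency graph merging superpixels whose mean depth
is within 25 mm (configurable; 0 keeps the single seed superpixel) of the
seed's. A plausibility flag marks selections that are not nearer the sensor
than the surrounding background — the failure mode when the plant sits far
off-centre.

## Evaluation

R² = 1 − SSE/SST against the 1:1 line (not squared correlation); NRMSE =
100·RMSE/mean(observed) % (mean normalization; range/sd modes would scale the
printed numbers but not the ordering, and the normalizer is configurable in
principle — the identity R² = 1 − (NRMSE/100)²·mean²/var is asserted on every
report row). Reports carry the model × trait grid, per-cultivar strata, and
the raw predicted-vs-actual pairs. The generalization protocol applies a
fitted model to a disjoint second-season sample set with zero refitting
(id overlap is an error; a weights hash verifies no side effects).

## Numerical and degenerate-input choices

- Split rounding: half-up globally, largest-remainder per stratum; stratum
  coverage floors take precedence over the exact global count when they
  conflict (only possible with many strata of size ≤ 2).
- Standardization guards: a zero-variance target column gets sd = 1, so a
  constant-target fit is well-defined.
- NaN/inf training loss aborts with a diagnostic rather than continuing.
- Batch size larger than the dataset is clipped with a warning.
- Constant depth maps return the centre superpixel with a warning; negative
  canopy heights clamp to 0 with a warning.
- Constant features are skipped (warning) by the Pearson screen; a constant
  target is an error.
- GLCM of an empty pair set (single masked pixel) is defined as the
  single-entry matrix (energy 1, contrast 0).

## Known limitations

- The NumPy network trains on CPU only; the full-width reference
  configuration at batch 128 is functional but slow (hours, not minutes, for
  300 epochs), which is why the scaled benchmark exists.
- Superpixel extraction assumes one centred plant; multi-plant scenes are out
  of scope.
- Synthetic-to-real transfer is untested by construction; the generator's
  occlusion and illumination models are stylized.
- SVR/RF hyperparameters (rbf kernel, C = 10, ε = 0.1; 500 trees, unlimited
  depth) are sensible defaults, not tuned per dataset; tuning would use the
  validation split, never test.
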