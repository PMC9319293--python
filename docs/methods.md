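# Methods

## Problem and model

Radial-probe endobronchial ultrasound (EBUS) places a rotating 20 MHz
transducer inside the airway, giving a 360° B-mode view with the probe at
the image center and the lesion echotexture around it.  Malignant lesions
tend to show a heterogeneous pattern — hyperechoic dots and arcs, anechoic
(necrotic) patches — while benign lesions appear homogeneous.  `ebusml`
classifies a lesion as benign (0) or malignant (1) by fusing three models:

1. **Tabular model (P1).**  An 89-entry vector per lesion: 85 radiomics
   values (9 shape-2D, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM, and
   the AWS heterogeneity feature) plus 4 clinical values (gender, smoking
   history, age, lesion-size category).  Features with positive mutual
   information against the label are kept and feed a random forest
   (1000 trees, Gini impurity, min-samples-split 2).  P1 is the fraction of
   trees voting malignant.
2. **Whole-image model (P2).**  A frozen convolutional trunk with a
   trainable softmax head (transfer learning).  The head is trained with
   SGD, learning rate 1e-4, cross-entropy, batch size 32.
3. **Patch model (P3).**  32×32 windows tiled inside the annulus 2–5 mm
   beyond the probe surface, classified independently by a four-stage CNN
   (8/16/32/64 kernels of 3×3; conv → batch-norm → ReLU → 2×2 max-pool →
   dropout; dense 256 → dense 2 → softmax; Adam, lr 1e-3, batch 128).
   With nM malignant and nB benign patch verdicts,
   `P3 = nM / (nM + nB)`, and the patch model calls the image malignant iff
   `P3 > T` with `T = 0.63`; equality stays benign.

The fused probability is `P = w1·P1 + w2·P2 + w3·P3` with `w ≥ 0`,
`Σw = 1`; the image is malignant iff `P > c`, with equality benign.  The
published operating point is `w = (0.41, 0.08, 0.51)`, `c = 0.53`; the
package can also recalibrate `w, c` by exhaustive grid search (step 0.01 on
the simplex and the cutoff) maximizing training accuracy, tie-broken toward
the smallest cutoff, then the lexicographically smallest weight triple.
Because the simplex vertices are on the grid, the optimized training
accuracy can never fall below any single model's.

Reported metrics are accuracy, sensitivity (malignant recall), specificity
(benign recall), PPV, NPV — computed from the confusion counts and rounded
to two decimals only at report time — plus the trapezoidal AUC over the ROC
of the continuous fused probability.  Sensitivity on a set with no
malignant cases is reported as NA, never as 0.

## Preprocessing

* **Contrast stretch.**  On the normalized grayscale image, intensities
  below `L` map to 0, above `H` to 1, and `x**γ` in between; `L, H` default
  to the 1st/99th intensity percentiles and `γ = 1` (the exponent is
  exposed in config; nothing in the published pipeline fixes it).  A
  constant image raises a degenerate-contrast error.
* **Boundary detection.**  180 equally spaced radial rays from the probe
  center; each intensity profile is Gaussian-smoothed (σ = 3 px), the probe
  disc is skipped (first drop below half the central brightness), the
  running maximum is restarted, and the boundary is the first sample that
  stays below 0.35 of the running maximum for 40 consecutive px, refined
  back to the half-maximum edge crossing.  Radii are circular-median
  filtered over angle (window 9) and the closed polygon is filled.  The
  persistence length is deliberately long: interior anechoic patches are
  transient dips, while the far field beyond the lesion stays dark
  indefinitely.  These defaults were calibrated once on held-out phantom
  seeds (Dice ≥ 0.96 across both classes) and then frozen.
* **Patch tiling.**  Ring radii are measured from the *probe surface*
  (probe radius default 2.0 mm): with 0.09 mm/px the 2–5 mm annulus is
  ≈ 33 px wide, admitting exactly one ring of 32 px windows.  A window
  qualifies when its four corner pixels lie inside annulus ∩ lesion mask
  (full containment of a 32 px square in a 33 px annulus is geometrically
  impossible — the inner edge midpoint always dips inward — so the corner
  rule is the workable reading); windows are accepted greedily in row-major
  origin order without overlap.  Coordinates are 0-based (row, col) with
  half-open windows.
* **Augmentation.**  Training split only; malignant images gain 90° and
  180° rotations (3× total), benign images additionally gain horizontal and
  vertical flips (5× total), with masks and labels transformed
  consistently.  Only lossless 90°-multiples and flips are used.  99
  malignant + 61 benign originals therefore become 297 + 305 = 602.

## Radiomics conventions

* Quantization: fixed bin count (32 levels) over the in-mask intensity
  range; a constant region maps to level 1.
* GLCM: distance 1, angles {0°, 45°, 90°, 135°}, symmetrized; features
  averaged over angles.  GLRLM uses the same four directions.  GLSZM zones
  and the GLDM/NGTDM neighbourhoods are 8-connected.  GLDM dependence
  counts the center plus neighbours whose level differs by at most α = 0.
  Entropies use log base 2.
* AWS: on the *unsymmetrized* normalized GLCM,
  `S_U = Σ_{i<j} p|i−j|`, `S_L = Σ_{i>j} p|i−j|`,
  `w = S_U/(S_U+S_L)` (0.5 when both vanish), `AWS = w·S_U + (1−w)·S_L`,
  averaged over the four angles.  AWS is 0 iff all co-occurrence mass is
  diagonal (perfect local homogeneity).
* Degenerate-region conventions: correlation on a zero-variance region is
  0; MCC is 1; NGTDM coarseness with zero total deviation is 1e6;
  busyness/strength with empty denominators are 0.  A single-pixel mask has
  maximum diameter 0 and elongation/sphericity 1.
* Clinical encoding: gender and lesion-size binary, smoking ordinal
  {non-smoker: 0, ex-smoker: 1, smoker: 2} (forests are invariant to
  monotone recodings), age in years.

Mutual information uses the plug-in contingency estimate for the three
categorical clinical columns and a k-nearest-neighbour estimator (k = 3)
for continuous columns; estimates above ε = 1e-6 count as positive.  If
nothing passes, the single best feature is kept with a warning.

## Neural-network stack

No GPU framework is used: the package ships a small numpy layer library
(same-padding conv via im2col, batch-norm, ReLU, 2×2 max-pool, dropout,
dense, softmax cross-entropy, SGD and Adam), verified against numerical
gradients in the test suite and fully deterministic given its seed on a
single thread.  The patch CNN follows the spatial path 32→16→8→4→2 with
2×2 pooling after every convolution, giving 91,074 parameters; patches are
instance-standardized (zero mean, unit variance per patch) so the
classifier sees echotexture rather than absolute brightness.

The whole-image model's production configuration names a densenet169 trunk
pretrained on natural images; constructing it requires an external weights
asset, so requesting it raises a clear error.  The first-class tested
configuration is the `small-test-backbone`: a seeded, frozen, randomly
initialized four-stage conv trunk over 64×64 inputs whose global-
average-pooled features (standardized with training statistics) feed the
trainable softmax head.  Random convolutional features are a weak but real
feature extractor; accordingly the calibrated ensemble typically assigns
this model a small weight — mirroring the published operating point, where
the whole-image model also carries the smallest weight (0.08).

## Synthetic phantoms

Each phantom is a 776×776 8-bit frame at 0.09 mm/px: a bright probe disc
(radius 2.0 mm) at center, a lesion bounded by a randomized star-convex
polygon (base radius 9–12 mm, low-order harmonic wobble ≤ 8%), and a dark
far field.  Texture is multiplicative Rayleigh speckle smoothed with a
small Gaussian kernel — standard B-mode phantom practice.  Benign defaults
are stationary speckle (grain 1.2 px); malignant defaults add hyperechoic
dots (1.8 per 1000 lesion px), three bright arcs, 10% anechoic area, and a
finer grain (0.8 px).  The grain difference is what separates the classes
at the single-patch level once patches are instance-normalized; the margin
(mean per-patch GLCM contrast ≈ 14 benign vs ≈ 20 malignant) was
established empirically once and the defaults frozen.

Patient metadata is drawn class-conditionally from the published cohort
statistics: malignant — 74/124 male, age N(64.32, 13.21²), 75/124 lesions
≥ 3 cm, smoking 52/35/37 (non/current/ex); benign — 29/76 male,
N(57.63, 15.51²), 38/76 ≥ 3 cm, 29/27/20.  Ages are clipped to 17–86
years.  The split is stratified 80:20, reproducing 99 + 61 training
originals at the default class sizes (124/76).

What the phantoms do **not** emulate: acoustic shadowing and attenuation,
probe contact artifacts, air bronchograms, anatomy outside the lesion,
inter-scanner variability, and any correlation between metadata and image
appearance beyond the class label.  Passing the synthetic end-to-end check
therefore demonstrates that the pipeline is wired correctly and can learn
the texture/metadata structure it assumes — not that it reaches any
particular accuracy on clinical images.

## Problem sizes and determinism

The synthetic end-to-end run uses the full published cohort shape (124/76,
80:20) with the small-test-backbone; it completes in a few minutes on one
CPU core.  Unit tests use smaller phantoms (320 px canvas, identical
probe/ring geometry) and reduced forests/epochs.  One global seed fans out
to per-module seeds through fixed offsets (+11 forest, +23 whole-image,
+37 patch CNN), so each model is reproducible in isolation; all randomness
flows through `numpy.random.Generator` and seeded scikit-learn estimators,
and every generator output is a pure function of its spec and seed.

## Known limitations

* The ray-cast boundary detector is a documented stand-in for the original
  ray-tracing reference, calibrated on phantoms only.
* The AWS formula follows its published name and heterogeneity semantics;
  the authors' exact prior-work definition is not public and small
  deviations are possible.
* The exact nine shape-2D feature names and the gray-level count of the
  original pipeline are unstated; this package's choices are documented
  above rather than inferred as the authors' intent.
* With very small lesions the annulus may admit no window; the patch model
  then abstains and the ensemble renormalizes (w1, w2) — the published
  observation that few-patch lesions are fragile applies here too.
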