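# ebusml

Weighted-ensemble classification of pulmonary lesions as benign or
malignant in radial-probe endobronchial ultrasound (EBUS) images, for
researchers building computer-aided diagnosis pipelines on small ultrasound
datasets.

Radial-probe EBUS shows the transducer at the image center with the lesion
echotexture around it.  `ebusml` fuses three complementary classifiers by
weighted soft voting:

* **P1 — radiomics + clinical random forest.**  89 features per lesion
  (9 shape-2D, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM, the AWS
  upper/lower-triangular GLCM heterogeneity feature, and 4 clinical
  values), filtered by mutual information (keep MI > 0) and fed to a
  1000-tree random forest; P1 is the fraction of trees voting malignant.
* **P2 — whole-image transfer classifier.**  A frozen convolutional trunk
  with a trainable softmax head (SGD, lr 1e-4, cross-entropy, batch 32).
* **P3 — patch CNN with ratio aggregation.**  32×32 windows tiled in the
  2–5 mm annulus around the probe, classified independently by a small CNN
  (8/16/32/64 kernels); with nM malignant and nB benign patch verdicts,
  P3 = nM/(nM+nB) and the patch model votes malignant iff P3 > T (T = 0.63).

The fused malignancy probability is

    P = w1·P1 + w2·P2 + w3·P3,   w_i ≥ 0,  w1 + w2 + w3 = 1,

with class malignant iff P > c.  The published operating point is
w = (0.41, 0.08, 0.51), c = 0.53; the package can also recalibrate both by
exhaustive grid search maximizing training accuracy.  Reported metrics are
Acc, Sen, Spec, PPV, NPV and the trapezoidal ROC AUC.

A seed-reproducible phantom generator (bright probe disc, star-convex
speckled lesion, class-conditional echotexture and patient metadata
matching the published cohort statistics) makes every stage runnable and
testable without clinical data.  See `docs/methods.md` for the model
conventions and the phantom's scope.

## Worked example

`examples/` contains one short script per capability.  Feature extraction
(`examples/03_radiomics_vector.py`) on one benign and one malignant
phantom prints:

```
benign    glcm_contrast=  5.192  glcm_aws=0.7457  ngtdm_busyness=6.755  shape_sphericity=0.949
malignant glcm_contrast= 10.015  glcm_aws=1.0602  ngtdm_busyness=5.049  shape_sphericity=0.949
vector length: 89
```

The heterogeneous malignant texture roughly doubles the co-occurrence
contrast and raises AWS, while shape descriptors stay put (both phantoms
share the same boundary).  The end-to-end script
(`examples/04_full_pipeline.py`) trains all three models on a 34-phantom
cohort and prints the test-split evaluation:

```
optimized weights (0.02, 0.0, 0.98), cutoff 0.01
test confusion: TP=4 FN=0 FP=0 TN=3
  accuracy     100.0
  sensitivity  100.0
  ...
```

Here the calibration puts nearly all weight on the patch model — on
phantoms the texture classes are cleanly separable, so single models can
already reach the grid-search optimum.

A thin CLI wraps the same library calls:

```sh
ebusml simulate --out cohort/ --n-malignant 124 --n-benign 76 --seed 1
ebusml full-run --out results/ --seed 1
```

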