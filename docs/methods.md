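# Methods

## Problem and workflow

The package classifies herbal-medicine samples into storage-age classes
from near-infrared diffuse-reflectance spectra measured on two surfaces of
the same sample (outer skin and inner capsule).  The workflow is the
standard chemometric screening design: spectra are pretreated to remove
baseline and scatter artifacts, partitioned once by Kennard–Stone into
calibration and test sets at a 2:1 proportion, and classified either
per-sensor or after fusing the two sensors.  Two fusion constructions are
used: low-level fusion concatenates the pretreated spectra (n x 2m) and
feeds SIMCA; mid-level fusion concatenates per-sensor PCA score blocks
(30 components each, n x 60) and feeds FLD.  Accuracies are reported per
class and pooled, in percent to two decimals.

## Models

**PCA.** Calibration spectra are mean-centred; loadings are the top-k right
singular vectors; explained-variance shares come from the squared singular
values.  At study scale (133 calibration spectra of 2,204 channels) 30
components explain ≥ 99% of the variance, because the artifact model
(scatter + quadratic baseline) spans only a handful of directions.

**SIMCA.** One PCA submodel per class.  The per-class residual variance is
the classical per-degree-of-freedom estimate
`s₀² = RSS / ((n_c − k − 1)(m − k))`, floored at 1e-12 for degenerate
(duplicated-row) classes.  A sample's distance to a class is its mean
squared orthogonal residual per residual channel, scaled by `s₀²`.
Assignment is the argmin over classes (forced assignment) rather than an
acceptance-region decision: forced assignment makes per-class accuracies of
0% expressible and matches how screening tables are tallied.  The score
leverage term of extended SIMCA variants is deliberately omitted; the
residual-only distance is the simplest classical form and is pinned by the
projection-residual oracle tests.  Per-class component counts default to
the smallest k explaining ≥ 95% of within-class variance, capped at 10.

**FLD.** Fisher directions are the leading generalized eigenvectors of
`S_b w = λ S_w w` (between vs within scatter), computed on PCA scores, with
unit-norm columns, deterministic sign, and at most (classes − 1) = 4
directions for the five-class problem.  A near-singular `S_w` receives a
ridge `1e-8·trace(S_w)/d` on its diagonal.  Prediction is nearest centroid
in discriminant space; ties break to the first class in sorted order.
FLD is run on 30 PCs per sensor (60 after fusion), keeping the sample:
variable ratio in the conventional 3–5x range.

## Pretreatment choices

The literature names the operators but rarely their parameters; the
definitions used are the standard chemometrics ones, each pinned by a
contract test:

* **de-bias** — per-spectrum mean removal (the simplest bias correction);
* **detrend** — per-spectrum removal of the least-squares straight line
  against channel index (first-order detrend);
* **SNV** — per-spectrum standardization, n−1 denominator;
* **MinMax** — per-spectrum scaling to [0, 1];
* **MSC** — per-spectrum regression `x ≈ a + b·ref` against the calibration
  mean spectrum, correction `(x − a)/b`; test spectra always reuse the
  calibration reference;
* **derivatives** — Savitzky–Golay, default window 15 channels, polynomial
  order 2 (common NIR practice); edges are handled by evaluating the
  polynomial fitted to the nearest full window, so length is preserved;
* **CWT** — single-scale continuous wavelet transform with a Mexican-hat
  (second derivative of Gaussian) mother wavelet, default scale 20
  channels.  Coefficients are the direct discretised convolution with the
  sampled wavelet (support ±8 scales, mirrored edges), with the sample mean
  subtracted from the filter so it is exactly zero-mean: constants map to
  zero everywhere and straight lines to zero away from the edges.

Composite recipes apply the operator named first, first (`cwt_msc` = CWT
then MSC; `der1_dt` = 1st derivative then detrend), with any MSC reference
fitted on the transformed calibration set at that stage.  All index-based
operators use unit channel spacing rather than Δwavenumber; on the uniform
grid this is a global scale factor that the classifiers absorb.
Pretreatment is applied per sensor *before* fusion — an MSC regression
across the sensor seam would be physically meaningless.

## Kennard–Stone partitioning

Euclidean max-min selection with the classic two-point seed; all ties break
to the lowest index, making the split fully deterministic.  The default
workflow splits on the two sensors' raw spectra concatenated, so both
sensors (and the fused dataset) share one partition; per-sensor splitting
is available by calling the splitter on a single sensor.  The
implementation is checked against an exhaustive O(n²) oracle.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the chemistry.  Each class's noiseless spectrum is a sum of six Gaussian
bands centred in the canonical NIR band-group ranges (9000–8000, 7300–6000,
6000–5500, 5400–4980, 4980–4500, 4500–4150 cm⁻¹) with class- and
sensor-specific amplitude offsets.  Observed replicates add, per sample:
a multiplicative scatter factor `1 + N(0, 0.05)`, a random quadratic
baseline with coefficient SD 0.03, and i.i.d. channel noise of SD 5e-4
absorbance units (typical FT-NIR noise); three replicates are averaged, as
in routine acquisition.  Amplitude trajectories rise to mid-age and then
fall, mirroring the non-monotone metabolite trends reported for aged
citrus pericarp.

Two structural properties are built in deliberately:

* **artifact dominance in raw data** — baseline and scatter variance
  swamps the class signal, so raw 2-PC scores do not separate classes
  (silhouette ≈ −0.05) and raw-spectrum classification is mediocre;
* **sensor complementarity** — the outer-skin effects are identical for
  the 20- and 25-year classes, and the inner-capsule effects for the 10-
  and 15-year classes, so each single sensor tops out near 80% whole-data
  accuracy while the fused data is fully separable.

Artifact magnitudes were calibrated once so that the pipeline reproduces
the qualitative regime the method is known for — second-derivative–FLD and
CWT+MSC–FLD fusion reach 100% test accuracy while raw-spectrum SIMCA stays
in the ~55–90% band — and then frozen.  Exact accuracies of the original
physical study are not targets: that data is not deposited, and Gaussian
bands with a low-dimensional artifact model are far simpler than real
pericarp spectra (no asymmetric band shapes, no within-class chemical
variability, no instrument drift between sessions).  Passing tests
therefore demonstrate correctness of the algorithms and the qualitative
fusion behaviour, not field performance on real material.

## Numerical choices and degenerate inputs

* Standard deviations use the n−1 denominator throughout.
* SNV/MinMax raise a named-sample error on constant rows; MSC raises on
  regression slopes below 1e-12.
* PCA loading signs are fixed (largest-magnitude element positive) so
  repeated fits are bit-identical.
* SIMCA residual variances are floored at 1e-12.
* All randomness flows from a single master seed through per-sensor child
  streams (`numpy.random.SeedSequence.spawn`), so a sensor can be
  regenerated independently and runs are bit-reproducible.

## Problem sizes

Tests exercise the full study scale (200 samples x 2,204 channels x 2
sensors) for the end-to-end checks, with 20 replicate master seeds for the
stochastic acceptance properties; unit and oracle tests use small matrices
(n ≤ 50) where brute-force references are exact.  The acceptance script
averages 5 replicate seeds at full study scale.

## Known limitations

* SIMCA omits the score-leverage term and class-specific F-test acceptance
  limits; the residual-only, forced-assignment variant cannot flag
  outliers or produce "none of the classes" answers.
* The composite-recipe order convention (named first = applied first) for
  "1st DT" is one of two defensible readings; the runner accepts any
  recipe list, so the other order can be screened explicitly if desired.
* The generator's within-class variability is purely instrumental
  (scatter/baseline/noise); real material also varies chemically within a
  class, which typically lowers all accuracies proportionally.
* JCAMP-DX/SPC formats, wavelength selection, PLS-family regression and
  cross-validated model selection are out of scope.
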