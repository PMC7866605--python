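# nirfusion

Two-sensor near-infrared (NIR) spectra classification with data fusion,
built for the authentication of aged herbal-medicine material — the
motivating case is dried citrus pericarp (Chenpi), whose market value rises
with storage age while its appearance barely changes.  A sample is measured
by diffuse reflectance on two surfaces ("sensors"): the outer skin and the
inner capsule.  Each surface carries partial, complementary chemical
information, and only their combination separates all age classes.

The package provides the full chemometric workflow:

* **spectra I/O** — a labelled `SpectraSet` container (n samples x m
  wavenumber channels, class labels, sensor tag) with a plain-CSV dialect;
* **pretreatment** — 14 recipes: `original`, de-bias, detrend (DT), SNV,
  MinMax, MSC, Savitzky–Golay 1st/2nd derivatives, single-scale Mexican-hat
  CWT, and the compositions 1stDer+DT, 1stDer+SNV, 1stDer+MSC, CWT+SNV,
  CWT+MSC;
* **partitioning** — deterministic Kennard–Stone max-min selection at a 2:1
  calibration:test proportion (200 samples → 133 / 67);
* **classifiers** — PCA, SIMCA (one PCA model per class, scaled orthogonal
  residual distance `d(x,c) = (‖r‖²/(m−k)) / s₀²` with forced argmin
  assignment) and Fisher's linear discriminant (FLD: leading generalized
  eigenvectors of the between-/within-class scatter pencil S_b w = λ S_w w,
  nearest-centroid prediction);
* **fusion** — *low-level* (spectra concatenated to n x 2m, fed to SIMCA)
  and *mid-level* (30 PCA scores per sensor concatenated to n x 60, fed to
  FLD);
* **synthetic data** — a seeded generator of realistic two-sensor spectra
  (5 age classes x 40 samples, 2,204 channels over 12,000–3,500 cm⁻¹, six
  Gaussian absorption band groups, multiplicative scatter, quadratic
  baseline drift, channel noise, triplicate averaging) with the
  discriminative information deliberately split across the sensors.

## Worked example

```python
import numpy as np
from nirfusion import (GeneratorConfig, generate, kennard_stone,
                       default_cal_size, run_experiment, results_table)

outer, inner = generate(GeneratorConfig(seed=1))      # 200 x 2204 per sensor
part = kennard_stone(np.hstack([outer.intensities, inner.intensities]),
                     default_cal_size(outer.n))       # 133 cal / 67 test
ci, ti = list(part.cal_indices), list(part.test_indices)
results = run_experiment(outer.subset(ci), outer.subset(ti),
                         inner.subset(ci), inner.subset(ti),
                         grid=["original", "der2", "cwt_msc"],
                         classifiers=("fld",))
print(results_table(results).to_string(index=False))
```

prints

```
      dataset pretreatment classifier  acc_5  acc_10  acc_15  acc_20  acc_25  whole
   outer_skin     original        fld  100.0  100.00  100.00   50.00   52.94  77.61
inner_capsule     original        fld  100.0   37.50   57.14  100.00  100.00  80.60
  combination     original        fld  100.0  100.00  100.00  100.00  100.00 100.00
   outer_skin         der2        fld  100.0   93.75  100.00   71.43   52.94  80.60
inner_capsule         der2        fld  100.0   50.00   57.14  100.00  100.00  83.58
  combination         der2        fld  100.0  100.00  100.00  100.00  100.00 100.00
   outer_skin      cwt_msc        fld  100.0  100.00  100.00   42.86   17.65  67.16
inner_capsule      cwt_msc        fld  100.0   56.25   28.57  100.00  100.00  82.09
  combination      cwt_msc        fld  100.0  100.00  100.00  100.00  100.00 100.00
```

Per-class columns are percent of test samples of that storage age (in
years) classified correctly; `whole` is the pooled test accuracy.  The
outer skin cannot resolve 20 vs 25 years and the inner capsule cannot
resolve 10 vs 15 — each tops out near 80% — while the mid-level fused
scores classify all 67 test samples correctly.

The same workflow is available from a shell:

```bash
nirfusion generate --seed 1 --out-prefix spectra
nirfusion split spectra_outer.csv spectra_inner.csv --out partition.csv
nirfusion run spectra_outer.csv spectra_inner.csv --partition partition.csv \
    --out results.csv
nirfusion report results.csv
```

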