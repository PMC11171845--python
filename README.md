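# nircal

Chemometric calibration of near-infrared (NIR) spectra for antioxidant
activity of powdered herbal material — ABTS and DPPH radical-scavenging
capacity (% clearance) and FRAP ferric-reducing power (µmol/L FeSO₄
equivalents). The package is aimed at chemometricians and food/herbal
quality labs who want a tested, scriptable version of the standard
workflow: scatter-correcting pretreatments, outlier screening, sample-set
partitioning, partial least squares (PLS) calibration, wavelength
selection, and a full validation battery — plus a synthetic-spectra
generator that provides reproducible study conditions with a known ground
truth.

## The methods at its core

* **PLS1 (NIPALS).** On column-centered X and centered y, each latent
  variable takes weights w ∝ Xᵀy, scores t = Xw, loadings p = Xᵀt/tᵀt,
  q = yᵀt/tᵀt, then deflates X by tpᵀ; the regression vector is
  b = W(PᵀW)⁻¹q. Latent-variable count by 10-fold cross-validation
  (venetian blinds), argmin RMSECV.
* **Pretreatments.** SNV (per-spectrum standardization), MSC (regression
  on a frozen calibration-mean reference), Savitzky–Golay smoothing and
  first derivative (1D+SG), and raw passthrough.
* **Sampling.** Mahalanobis outlier screening in a PCA score subspace with
  a Chauvenet-style rule (flag when n·P(D > dᵢ) < ½); Kennard–Stone
  max–min partitioning into calibration and prediction sets.
* **CARS** (competitive adaptive reweighted sampling): N = 100 Monte Carlo
  runs; each fits PLS on an 80% subsample, force-keeps the ⌈rᵢ·p⌉
  largest-|b| wavelengths under the exponentially decreasing function
  rᵢ = (p/2)^(1/(N−1))·e^(−i·ln(p/2)/(N−1)), then resamples wavelengths
  with probability |bⱼ|/Σ|b| (adaptive reweighted sampling). The subset
  with minimal 10-fold RMSECV over runs wins.
* **GA-PLS:** binary-chromosome genetic algorithm (tournament selection,
  single-point crossover, bit-flip mutation, elitism) with −RMSECV
  fitness; wavelengths are selected by their frequency across the best
  chromosomes of many independent runs.
* **Validation:** R²C/R²P (squared Pearson), RMSEC/RMSECV/RMSEP, slope,
  Roy's r²m = r²·(1 − √(r² − r²₀)), and y-randomization with
  cR²P = √(R²C)·√(R²C − R²rand); gates at 0.5 for r²m and cR²P.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from nircal import SyntheticConfig, simulate, PipelineConfig, run_selector_comparison
from nircal.selection import CarsConfig, GaConfig

config = PipelineConfig(
    analytes=("abts",),
    cars=CarsConfig(n_runs=100, max_lvs=15),
    ga=GaConfig(n_runs=10, population=16, generations=10,
                n_repeats=1, frequency_threshold=2, cv_folds=5, max_lvs=10),
    seed=3,
)
out = run_selector_comparison(config)
print(out["table"].to_string(index=False))
for analyte, s in out["summary"].items():
    print(f"{analyte}: RMSEP decrease {s['pct_rmsep_decrease']:.2f}%")
```

which prints (about a minute on one core):

```
analyte   method  LVs  variables   R2C  RMSEC  RMSECV  slope_cal  R2rand  cR2P   R2P  RMSEP  slope_pred   r2m
   abts full_pls    7       1557 0.967   0.14    0.23       0.97   0.141  0.89 0.873   0.29        0.72 0.739
   abts   ga_pls    8        750 0.977   0.12    0.20       0.98   0.166  0.89 0.867   0.30        0.71 0.737
   abts cars_pls   12         58 0.999   0.03    0.06       1.00   0.141  0.93 0.852   0.28        0.76 0.779
abts: RMSEP decrease 6.10%
```

Reading the table: each row is one model; `R2C`/`RMSEC` describe the
calibration fit, `RMSECV` the cross-validated error that chose the
latent-variable count (`LVs`), `R2P`/`RMSEP`/`slope_pred` the held-out
prediction quality, and `R2rand`/`cR2P`/`r2m` the chance-correlation
battery (both gates want ≥ 0.5). `variables` is how many wavelengths the
model uses — wavelength selection aims to shrink it from 1557 to tens
while improving RMSEP.

The numbered scripts under `analysis/` run the same study stepwise
(simulate → outliers/split → pretreatment comparison → wavelength
selection → selector comparison → published-arithmetic regression) and
write their tables under `results/`.

A command-line interface mirrors the pipeline stages:

```bash
nircal simulate --n-samples 111 --seed 0 --out-spectra s.csv --out-references r.csv
nircal train --spectra s.csv --references r.csv --analyte abts --preprocess snv --out-model m.json
nircal evaluate --model m.json --spectra s.csv --references r.csv
```

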