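# Methods

`nircal` implements a complete near-infrared (NIR) calibration workflow for
predicting antioxidant activity of powdered herbal material — ABTS and DPPH
radical-scavenging capacity (percent clearance) and FRAP ferric-reducing
power (µmol/L FeSO₄ equivalents) — together with a synthetic-data generator
that stands in for the kind of 111-sample, 1557-wavelength data set such
studies are built on. This note records the models, the conventions chosen
where the field leaves room, and what the synthetic study conditions do and
do not establish.

## Assay arithmetic

Radical-scavenging assays report clearance capacity
`100·(A₀ − (A₁ − A₂))/A₀`, where A₀ is the blank (radical solution alone),
A₁ the sample mixed with the radical solution, and A₂ the sample's own
absorbance. The formula is implemented unclamped: physically implausible
absorbances can produce values outside [0, 100], and we surface them rather
than hide them. FRAP is read off a linear standard curve
`A = 0.0019·c + 0.0044` (validated 50–500 µM); inversion outside that range
sets an out-of-range flag instead of raising.

## Synthetic study conditions

The generator emulates diffuse-reflectance FT-NIR spectra of plant powder:

* **Axis.** 1557 points uniform in wavenumber from 10000 to 4000 cm⁻¹,
  stored ascending in nm (1000–2500 nm). The FT-instrument convention
  reproduces the 1557-variable count typical of this configuration.
* **Chemistry.** Latent components with Gaussian absorption bands. Three
  assay-active constituents sit at the canonical hydrogen-bond positions
  (O-H: 1440/1940 nm; C-H overtones: 1210/1730 nm; C-H/CH₂ combinations:
  2280/2330 nm) with band widths of 14–22 nm. The inert matrix comprises a
  broad residual-moisture component (1410/1905 nm, widths 70–80 nm) and ten
  minor constituents with two narrow bands each at fixed quasi-random
  positions kept ≥ 45 nm from the informative centers. Concentrations are
  drawn uniformly per component and normalized to sum to one
  (`compositional=True`): assay values are per-mass quantities, so they
  must depend on relative composition, while absolute signal magnitude is a
  packing/path-length artifact. Without this, scatter correction (which
  removes per-spectrum magnitude) would destroy the y-relevant signal — the
  opposite of how these pretreatments behave on real data.
* **Scatter.** Each spectrum is multiplied by a smooth per-sample field
  `(1 + m)·(1 + t·u(λ) + c·q(λ))` with a flat gain m (sd 0.10) and
  centered linear/quadratic terms u, q scaled by t, c ~ N(0, 0.8); an
  additive offset (sd 0.05 AU) and white detector noise (sd 5 mAU) follow.
  The wavelength-dependent part matters: particle-size scatter in diffuse
  reflectance is never spectrally flat, and SNV/MSC remove only its flat
  component. In development we verified that with purely flat scatter the
  full-spectrum model is never beaten by any wavelength subset — not even
  by an oracle given the planted informative bands — because latent-variable
  truncation alone then regularizes it perfectly; low-order wavelength
  dependence restores the regime in which wavelength selection pays off,
  which is the regime these studies report.
* **References.** For each analyte, an effect-weighted sum of the active
  concentrations is mapped affinely into a realistic assay range
  (ABTS 7.4–11.7 %, FRAP 14.0–47.7 µmol/L, DPPH 11.4–30.2 %), leaving a
  margin of four assay-noise SDs at each edge, then assay noise
  N(0, 0.03·range) is added. All three active components contribute to all
  three assays with different weights.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  configs give bit-identical outputs. The ground truth (per-component
  informative windows of ±2 band widths, latent concentrations) is returned
  alongside and can be written as a JSON sidecar.

What this generator does **not** model: instrument line shape and
apodization, band shifts with temperature or moisture, nonlinear
detector response, reagent kinetics, replicate structure of the wet-lab
assays, and batch/origin clustering. Passing the multi-seed property suites
therefore shows that the algorithms behave correctly in a controlled regime
with a known answer — not that any particular accuracy would be attained on
real spectra.

## Pretreatments

* **SNV** standardizes each spectrum to mean 0, sd 1 (n−1 denominator);
  constant spectra are an error naming the sample.
* **MSC** regresses each spectrum on a reference (OLS with intercept) and
  rescales; the reference is the calibration column-mean, frozen at fit
  time and reused verbatim for prediction spectra so no prediction-set
  statistic ever enters the transform.
* **SG smoothing / first derivative** use Savitzky–Golay filters
  (default window 11, polyorder 2 — conventional; nothing in the workflow
  is sensitive to the exact choice, and both are exposed). The derivative
  is taken per index and divided by the local nm step, since the axis is
  uniform in wavenumber and thus mildly non-uniform in nm; boundary windows
  use the polynomial edge fit, so length is preserved. "Smoothing" as a
  standalone pretreatment means SG smoothing with the same defaults.

## Outlier screening and partitioning

Mahalanobis distances are computed in the PCA score subspace retaining 99%
of variance (the raw wavelength covariance is singular for p ≫ n); squared
distances are chi-square(k) under normality. The default Chauvenet-style
rule flags a sample when `n·P(D > dᵢ) < ½` — the expected number of equally
extreme samples falls below one half; a fixed 95%-quantile rule is also
available because "Chauvenet at 95% confidence" mixes two conventions in
common usage. Screening runs once on the spectra before any modelling.

Kennard–Stone seeds with the most distant pair (Euclidean, on the same
pretreated spectra used for modelling) and greedily adds the max–min
sample; ties break to the lower input index, making the split fully
deterministic. The default calibration share is 2/3 with
`round(fraction·n)` selected — 74 of 111; a `calibration_size` override
(e.g. 75) is provided for compatibility with studies that quote 75/36,
a count `round` cannot produce from a 2:1 ratio.

## PLS core

PLS1 by NIPALS on column-centered X and centered y; no unit-variance
scaling (the NIR convention — variance structure is what the pretreatments
already address). Weights, loadings and the regression vector
`b = W(PᵀW)⁻¹q` are stored per model, and deflation stops early with a
logged warning if X is exhausted. Cross-validation uses venetian-blind
folds (sample i → fold i mod k; deterministic by default, shuffling
available behind a seed) and fits each training fold once at the maximal
latent-variable count, reading off nested predictions for every smaller
count. The chosen count is the RMSECV argmin, ties resolved toward fewer
latent variables. `folds = n` gives exact leave-one-out, verified against
brute-force refits.

## Wavelength selection

**CARS.** N = 100 Monte Carlo runs (the standard budget). Each run fits a
PLS model on a random 80% row subsample restricted to the active set
(latent variables by inner 10-fold CV, capped at 20), then prunes by (i) a
forced exponentially-decreasing-function cut keeping the
`⌈rᵢ·p⌉` largest-|b| wavelengths, with `rᵢ = a·e^(−k·i)`,
`a = (p/2)^(1/(N−1))`, `k = ln(p/2)/(N−1)` (so r₁ = 1 and the final run
keeps 2), and (ii) adaptive reweighted sampling: p draws with replacement
with probability `wⱼ = |bⱼ|/Σ|b|`, keeping the unique survivors. Drawing p
times (not `⌈rᵢ·p⌉` times) is essential: with the smaller draw count,
deduplication compounds with the EDF schedule and the active set collapses
to 2 variables within ~13 runs, which contradicts the canonical trajectory
(sharp drop over the first ~10 runs, gentle decline thereafter, RMSECV
minimum well before the last run). Each run's active set is scored by
10-fold RMSECV on the full calibration set; the run with the global minimum
wins. Per-run kept counts, RMSECV and the full-length coefficient path are
recorded for trajectory plots.

**GA.** Binary chromosomes over wavelengths; fitness is −RMSECV of PLS on
the active columns. Internals follow common GA-PLS toolbox defaults:
initialization probability 0.10 per gene, size-2 tournament selection,
single-point crossover (p = 0.5), bit-flip mutation (p = 0.01), one elite;
empty chromosomes are repaired by switching on one random gene, and fitness
values are cached per chromosome. A wavelength's *frequency* is the number
of independent runs whose best-ever chromosome contains it; wavelengths at
or above the frequency threshold (default 4) are selected. Because the GA
is stochastic, the whole procedure runs `n_repeats` times (default 5) and
the repeat with the median final RMSECV is reported (lower median for even
counts). The GA operates on individual wavelengths by default; an optional
`window` setting mean-bins that many adjacent wavelengths first and expands
the selected bins back to their member wavelengths.

**Scaled fixture budgets.** Multi-seed studies in the test suite and the
analysis scripts run CARS at its full budget (100 runs; it is cheap) but
scale the GA to 10 runs × 10 generations with population 16, one repeat,
5-fold inner CV and a latent-variable cap of 10, with the frequency
threshold scaled to 2 of 10 runs. These are the package's chosen study
sizes for 20-seed experiments; the full GA protocol (100 × 100,
population 30, five repeats, threshold 4) remains the library default.

## Validation battery

R² throughout is the squared Pearson correlation (the convention in NIR
calibration tables; the coefficient of determination is available as an
option). Slope is the OLS slope of predicted on measured, intercept
included; the direction is configurable since the literature uses both.
RMSE uses denominator n.

Two robustness statistics come from the QSAR validation literature, whose
printed formulas are frequently garbled in transcription; we use the
standard forms and verified them against 24 published benchmark rows
(maximum deviation 0.005):

* **Roy's r²m** `= r²·(1 − √(r² − r²₀))`, with r²₀ the through-origin
  determination using `k = Σ(y·ŷ)/Σ(ŷ²)`. If numerical noise makes
  r² < r²₀ the absolute difference is used under a logged warning.
  Gate: r²m ≥ 0.5.
* **cR²P** `= √(R²C)·√(R²C − R²rand)`, where R²rand is the mean calibration
  R² over null refits on permuted responses (default 25 permutations,
  seeded), on the same wavelength subset as the real model.
  Gate: cR²P ≥ 0.5.

The null protocol matters more than it looks. Forcing every null refit to
the real model's latent-variable count measures the interpolation capacity
of that many components — for p ≫ n this is large (often R² > 0.5 even at
modest counts; with p white-noise columns the noise Gram matrix ≈ σ²p·I
feeds a component proportional to the permuted target into every score),
and it cannot produce the near-zero null levels benchmark tables print at
14–18 latent variables. The default here is therefore the working
analyst's protocol: rerun the whole modelling procedure on the scrambled
response, letting cross-validation re-choose the component count in
1..n_lvs. On scrambled data CV collapses to very few components and the
null calibration R² stays near zero, matching published magnitudes. The
fixed-count variant remains available (`lv_selection="fixed"`).

## Pipeline

The study driver chains: generate/load → Mahalanobis screen → per-method
Kennard–Stone split → Full-PLS over the five pretreatments per analyte
(winner = lowest RMSECV among gate-compliant rows) → GA/CARS selection on
the winning pretreatment's calibration set → evaluation reports per
(selector, analyte) → headline summary including the percent RMSEP decrease
of CARS-PLS versus Full-PLS, `100·(RMSEP_full − RMSEP_cars)/RMSEP_full`.
One master seed fans out to stage seeds through `numpy.random.SeedSequence`;
reruns are bit-identical. Any failing grid cell is recorded and skipped,
never fatal. Reports are JSON with full precision; comparison tables are
CSV rounded to table precision (3 dp for R²-like quantities, 2 dp for
errors and slopes).

## Known limitations

* The generator's linear Beer–Lambert mixing plus smooth scatter cannot
  produce the nonlinear matrix effects real powders show; selector
  improvements here are driven by finite-sample estimation noise and
  structured interference, which is one — not the only — mechanism on real
  data.
* On the synthetic fixture both wavelength selectors beat the full
  spectrum by a few percent of RMSEP, but their ranking relative to each
  other is within seed-to-seed noise at the scaled budgets; single-dataset
  comparisons of CARS against GA (here or in published tables) should not
  be read as a stable ordering.
* PLS1 only; multi-response PLS2, OPLS and kernel variants are out of scope.
* The Chauvenet rule is applied to spectra only, not per-analyte.
* GA results at the scaled fixture budget are noisier than the full
  protocol; the frequency threshold interacts with the number of runs and
  should be rescaled if `n_runs` changes materially.
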