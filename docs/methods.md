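# Methods note

This note records the models, parameter defaults and numerical choices in
`tamspatial`, and what the synthetic generator does and does not emulate.

## 1. Image front-end (`tamspatial.ihc`)

Tiles are modelled in optical density (OD): `OD = −log10(I / I_background)`
per channel, with the standard H-DAB unit vectors hematoxylin
(0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78). Stain separation is the
Moore–Penrose pseudoinverse of the stain matrix applied to the OD image with
negative amounts clipped to zero; on noise-free rendered tiles this is the
exact linear inverse of rendering (verified to 1e-6 in the tests). The
`StainModel` constructor rejects (near-)collinear stain vectors via the Gram
matrix, since the deconvolution is then ill-posed.

Detection: Gaussian smoothing (1.0 µm), `peak_local_max` seeds (minimum
peak distance 3 µm), watershed segmentation on the smoothed hematoxylin
channel, then region filtering to 10–400 µm² at 0.25 µm/px. A cell is
called marker-positive iff its mean DAB OD is ≥ 0.3 — a fixed-threshold
convention chosen so positivity is monotone in the threshold and
deterministic. These defaults give recall and positivity precision 1.0 on
rendered 50-cell tiles; they are *not* tuned for real slides, which have
noise sources (section thickness, stain variation, touching nuclei) the
renderer does not model.

## 2. Compartment geometry (`tamspatial.geometry`)

ROIs are squares of 1.96 mm² (side 1400 µm), five per case. Tumor nests are
arbitrary (multi)polygons inside the ROI. The peritumoral stromal band is
`dilate(tumor, 50 µm) − tumor`, intersected with the ROI, built with
`shapely.buffer(quad_segs=64)`; at that discretization the band area of a
circular nest differs from the closed-form annulus by < 0.01%. A cell is
*tumoral* if its distance to the tumor is 0 (boundary inclusive), *stromal*
if 0 < d ≤ 50 µm, otherwise excluded from densities. Distance to tumor is
the Euclidean point-to-set distance (0 inside a nest). The 50 µm width
follows the profiling convention that the immediately peritumoral stroma is
the biologically interactive compartment.

## 3. Case metrics (`tamspatial.metrics`)

Per-ROI densities are count/area (cells/mm²); a zero-area compartment yields
NaN with a warning rather than a silent 0. Case aggregation defaults to the
unweighted mean over ROIs (each ROI is an equally chosen field of view);
area-weighted aggregation is available. Mean distance-to-tumor is pooled over
the case's cells by default (a per-ROI-mean option exists). Dichotomization:
high ⟺ value > cohort median, ties low — with an even cohort and distinct
values this gives exact 50/50 splits, matching the reported group sizes.
Four-group scores combine the stromal and tumoral flags per marker;
ratio scores divide a TAM density by the stromal-TIL percentage (NaN with a
warning when sTIL = 0).

## 4. Statistics (`tamspatial.stats`)

* 2×2 and 2×k tables: Pearson chi-square **without** continuity correction.
* Ordered stratifiers with ≥ 3 rows (grade): linear-by-linear association
  (Mantel trend) test, M² = (n−1)·r² with integer scores, df = 1.
* Expected count < 5 in a 2×2 table: Fisher's exact test (probability-mass
  rule).
* These choices reproduce all twelve published contingency p-values at their
  printed precision (see `reference_tables` and the acceptance tests).
* Rank tests (Spearman, Mann–Whitney, Wilcoxon signed-rank) delegate to
  scipy with `method="auto"`: exact null distributions for small untied
  samples, tie-corrected normal approximation otherwise. The exact branch
  deviates from a plain normal approximation but is strictly more accurate;
  oracle tests enumerate the small-sample nulls.
* McNemar's test for paired flags uses the exact binomial distribution of
  discordant pairs.
* Type-I error of the battery is checked empirically: under simulated
  independence the 2×2 Pearson test rejects at 0.05 ± 0.01 (10,000 tables),
  and log-rank null p-values pass a Kolmogorov–Smirnov uniformity test.

## 5. Survival (`tamspatial.survival`)

Kaplan–Meier is the product-limit estimator; the k-group log-rank statistic
uses hypergeometric variances/covariances per event time, dropping the last
group and inverting with the pseudoinverse (so collinear degenerate cases do
not crash). Cox regression is a damped Newton solver on the partial
likelihood with **Breslow** tie handling by default (ties are rare with
continuous months; Efron is available and the two agree exactly without
ties). Model selection is backward elimination on Wald p-values with
p_remove = 0.10, matching the convention that borderline (0.05 < p < 0.10)
covariates are retained and reported. Convergence is declared at a gradient
norm of max(tol, tol·d) for d events (absolute 1e-8 is unattainable in
float accumulation at large n); fits with |β| > 15 or SE > 50 raise
`CoxConvergenceError` as monotone-likelihood/separation rather than
returning a meaningless estimate. All three estimators are cross-checked
against `lifelines` in the test suite; `lifelines` is a test-only
dependency.

## 6. Synthetic cohort (`tamspatial.synthetic`)

What it emulates: a ~225-case breast-cancer cohort with five 1.96 mm² ROIs
per case, tumor nests occupying 20–60% of each ROI, CD163+/CD206+ point
patterns in the tumor and band compartments, clinical covariates, and
exponential survival driven by a configurable risk flag.

* **Geometry**: 1–5 Fourier-perturbed elliptical nests per ROI, rejection
  sampled to the target tumor fraction.
* **Point patterns**: homogeneous Poisson within each compartment with
  case-level intensity; counts are Poisson(intensity × area) (verified by a
  goodness-of-fit test).
* **Intensities**: lognormal across cases (reported density ranges are
  heavily right-skewed), medians set to the reported cohort medians
  354.1 / 303.2 (stromal CD163/CD206) and 210.8 / 111.6 (tumoral), case
  log-sd 0.9 and ROI-level log-sd 0.15 (mean-corrected so ROI noise leaves
  case means unbiased). A Gaussian copula supplies a shared cross-marker
  factor (ρ = 0.5) and per-marker stromal–tumoral coupling, stronger for
  CD163 (τ = 0.45) than CD206 (τ = 0.10), reproducing the reported pattern
  that CD163 compartments correlate more strongly. Grade raises CD163
  intensities multiplicatively; the effect is centred at the population-mean
  grade (2.31 under the 7/55/38% grade marginals) so the configured medians
  remain population medians.
* **Clinical covariates**: marginals approximating the reported cohort
  (median age ≈ 48, ~76% ER+, ~46% node-positive, grade 7/55/38%); stromal
  TIL percentage shares the copula's common factor so it correlates
  positively with TAM densities.
* **Survival**: exponential event times with log-hazard ln(3.477) on the
  high stromal-CD163/sTIL-ratio flag (the reported dominant risk factor),
  uniform administrative censoring on (0, 143) months, relapse hazard scaled
  so DFS ≤ OS. The baseline hazard is **calibrated in closed form**:
  P(event) = 1 − (1 − e^{−λH})/(λH) per case under uniform censoring, solved
  with `brentq` so the expected event fraction hits the target 14.1% — no
  stochastic tuning loop.
* **Reproducibility**: every case draws from
  `SeedSequence((seed, case_index))` substreams, so a given case is
  byte-identical regardless of cohort size, and full outputs are
  byte-identical across runs with the same seed.

What it does **not** emulate: tissue-level spatial clustering of macrophages
(hotspots beyond compartment effects), cell-size/shape variation, stain
artefacts and noise, informative censoring, competing risks, and any
covariate–survival pathway other than the configured flags. Consequently
the generator validates the *measurement and inference machinery*, not
biological claims.

## 7. Open conventions resolved

* Distances are computed to the tumor nests of the cell's own ROI.
* Median cutoffs are computed on the full cohort (not per stratum), once,
  and reported alongside the flags.
* Ratio scores use the case-level (not ROI-level) density and sTIL values.
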