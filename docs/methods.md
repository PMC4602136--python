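# Methods

`strokecov` implements a longitudinal structural-covariance analysis of
gray-matter volume (GMV) change after sensorimotor stroke, together with the
synthetic data machinery needed to test every stage against known ground
truth. This note records the models, the conventions, and the design choices
made where the design was genuinely open.

## Analysis model

The pipeline follows a two-level design for both behavior and imaging.

**Behavior (response feature analysis).** Each patient's timed dexterity
series (PSO, picking small objects) is z-transformed against a healthy
control group and summarized by the better of two candidate trajectory
models,

- linear: `z(t) = a + b t`
- exponential: `z(t) = z∞ − (z∞ − z0) · exp(−t/τ)`,

selected by Akaike's information criterion `AIC = 2k + n ln(RSS/n)` with
`k = 2` (linear) or `k = 3` (exponential). Ties and non-convergent
exponential fits go to the linear family. The subgroup rule is: linear →
*fast*; exponential with asymptote `z∞ ≥ −2.5` → *slow*; `z∞ < −2.5` →
*impaired* (±2.5 z-units is the normal-performance band). A stricter
*fast* rule (linear **and** baseline within the normal band) is available
behind a flag. At the group level a column-centered (covariance, unscaled)
PCA of the completed patients × visits z-matrix yields per-patient
expression coefficients; components are retained by the Kaiser–Guttmann
criterion (eigenvalue above the mean eigenvalue over all thin-SVD
components). Missing visits are imputed by the across-patient mean at that
time point before the PCA; trajectory fits simply drop missing cells.

**Imaging (tensor-based morphometry + covariance PCA).** Local volume
change between two time points is the Jacobian determinant of the
deformation `x → x + u(x)` (central differences, one-sided at borders, so
affine mappings are exact everywhere), optionally modulated by a tissue
segmentation and smoothed with an isotropic Gaussian given by its FWHM
(`σ = FWHM/√(8 ln 2)`; the 12-mm default follows the convention of
volume-based morphometry pipelines). The masked scans × voxels matrix `X`
is **double centered**,

```
R_ij = X_ij − colmean_j − rowmean_i + grandmean,
```

so its row, column and grand means vanish (checked to 1e−10), then factored
by thin SVD `R = U S Vᵀ`. Rows of `Vᵀ` are *eigenimages* (unit-norm voxel
patterns), columns of `U` are the per-scan *expression coefficients*
(unit-norm, hence each coefficient lies in [−1, 1] and sums to ~0), and the
variance fraction of component *i* is `σᵢ²/Σσ²`. Double centering removes
one degree of freedom, so at most `min(scans, voxels) − 1` components are
non-null; numerically null trailing components are dropped. Unlike the
classic scaled-subprofile model no logarithm is taken before centering: the
change maps already live on a ratio-around-1 scale. The sign of each
component is fixed by making the eigenimage's largest-magnitude voxel
positive (configurable, so a particular anatomical orientation can be
imposed for reporting).

**Selection, clusters, overlap, association.** Components are screened
against external variables (behavioral expression, lesion volume, age) by
Pearson correlation, gated by the critical correlation
`r_crit = t/√(t² + n − 2)` at the Bonferroni-corrected two-tailed
per-comparison alpha (`α/m`, default 0.05/8 = 0.00625, reported rounded to
0.006). The selected eigenimage is thresholded at its 1st/99th in-mask
percentiles (linear-interpolation percentiles, inclusive tails so the
percentile voxel itself survives), connected components below the 32-voxel
extent threshold are discarded, and surviving clusters are intersected with
subgroup lesion-density maps (per-voxel lesioned fraction, binarized at a
strict > 20 %), reporting overlap in cc, percent-of-lesion-on-cluster and
percent-of-cluster-affected. Full-precision volumes are kept internally and
rounded to one decimal only in reports. Group contrasts use a Shapiro–Wilk
normality gate, Kruskal–Wallis across the three classes and Mann–Whitney U
for impaired vs. pooled recovered, all two-tailed. The hand-function model
is `y = β0 + β1·expression + β2·lesion volume + β3·(expression × lesion
volume)` by ordinary least squares (per-term t on n − 4 df, R², F(3, n−4));
a robust variant (Huber IRLS, tuning constant 1.345) is available behind a
flag and reports pseudo-R²/F computed from its residuals.

## Synthetic data: what it emulates, what it does not

**Cohort generator.** Three subgroups with the trajectory families above,
default split 8/12/8 (n = 28). The packaged 28-patient fixture
(`table1.csv`, frozen by SHA-256) transcribes its source verbatim; note
that textual subgroup counts for that cohort are reported inconsistently in
its source (8/10/8 vs. 8/12/8) — the generator keeps the 8/12/8 split that
actually sums to 28, and the fixture's median row is reproducible only for
some columns (age 65.5, PSO month-3 7.3, TOR month-9 30, NIHSS baseline 4
recompute exactly; a few other printed medians differ from the medians of
the printed per-patient values, e.g. HD baseline 20 vs. recomputed 19).
Class-parameter distributions are calibrated to the severity range of that
cohort: a timed task the patient can barely perform yields baseline z near
−40 (control PSO 6 ± 1 s), so exponential amplitudes are drawn U(3, 20)
(slow) and U(3, 30) with asymptote U(−10, −3) (impaired); fast patients are
linear with baseline U(−2, 0.5) and slope U(0, 0.004)/day; τ ~ U(30, 90)
days. Visit schedule: day 5 (baseline) then monthly to day 270 (10 visits).
Default measurement noise is 0.5 z-units; at that level the classifier
recovers ≈ 94 % of true classes (100 % without noise). A 10/280 fraction of
behavioral cells is blanked to emulate missed visits. z-orientation: timed
tests are flipped, `z = (control mean − value)/sd`, so worse performance is
more negative; force/count tests use `z = (value − mean)/sd`. NIHSS and mRS
are generated only as class-correlated ordinal summaries — no item
structure — and raw scores are continuous surrogates (no reaction-time
quantization), so passing tests say nothing about rounding effects in real
instruments.

**Volume-change generator.** Default grid 32³ at 2-mm isotropic voxels
inside a spherical brain mask (~11,500 voxels). The 2-mm resolution is a
reconstruction from the volumetric consistency of the cluster reports the
package mirrors (1362 voxels ↔ 10.9 cc ⇒ 8 mm³/voxel), not an independent
fact. Subject maps are `1 + Σ_k loading[s,k]·pattern_k + noise`: patterns
are smooth random fields (Gaussian-smoothed white noise at the analysis
FWHM), orthonormalized over the mask and scaled to unit RMS, so the stored
ground-truth patterns are exactly the patterns embedded in the delivered
maps; the noise is an independent smooth field rescaled so `noise_sd` is
its per-voxel sd *relative to the mean pattern-loading sd* (noise 0.1 =
10 % of pattern amplitude). Loadings can be given exact population
correlations with a behavioral vector and with log lesion volume by
constructing them in the span of the standardized targets plus an
independent residual. Lesion masks are spheres with class-typical centers
and log-normal volumes (medians ≈ 7.8/3.5/42.8 cc for fast/slow/impaired).
Real lesions are not spherical, real noise is not stationary, and real
registration error is absent — pattern-recovery results here bound what the
decomposition can do under ideal geometry, not under real data.

## Numerical choices

- **Exponential fitting** is separable nonlinear least squares: for fixed τ
  the model is linear in (z∞, amplitude), so a τ multi-start grid
  (5, 15, 30, 60, 120, 240 days, plus points scaled to the visit span) is
  scanned in closed form and the best τ refined by Brent search on ln τ.
  This is deterministic, has no convergence failures on non-degenerate
  input, and recovers noiseless parameters to ~1e−10.
- **AIC floor:** `RSS` is floored at 1e−30 before the logarithm so exactly
  interpolating fits remain comparable; the tie rule (linear wins within
  1e−9) then resolves them by parsimony.
- **Smoothing boundary** is reflective (`reflect`), which makes the
  smoothing operator symmetric and preserves the total sum to machine
  precision; gradients use one-sided differences at borders. Both are
  configurable.
- **Percentiles** use linear interpolation between order statistics, and
  thresholds are inclusive (≤ P1, ≥ P99); lesion-density binarization is
  strict (> 0.20). A constant eigenimage yields empty tails with a warning
  rather than an error.
- **Connectivity** default is 18 (face + edge), a common volumetric
  default; 6 and 26 are supported and the choice is logged in every run
  manifest.
- **Critical correlation:** the implementation reports the t-inversion
  value (e.g. r_crit ≈ 0.530 at α = 0.00625, n = 28, two-tailed). Reports
  derived from the cohort this package mirrors sometimes quote 0.466 for
  that setting; that value matches no standard one- or two-tailed
  inversion we could reconstruct, so it is documented here but never used
  as an oracle.
- **Degenerate inputs:** empty masks, empty ROIs, constant externals,
  all-missing visit columns, non-binary lesion masks and collinear designs
  raise informative errors (or warnings where the contract asks for them,
  e.g. non-positive Jacobian determinants are counted and warned about).
- **Determinism:** every generator takes an integer seed and splits it
  through `numpy.random.SeedSequence`; two runs of the pipeline with the
  same config produce bit-identical volumes and CSVs (verified by SHA-256
  in the run manifest, which excludes its own timestamps).

## Problem sizes

Default study conditions: n = 28 subjects (8/12/8), 10 visits, 32³ grid at
2 mm, 12-mm FWHM. The stochastic verification studies use 100 synthetic
datasets for pattern recovery (n = 28, loading–behavior correlation 0.8,
noise 10 %), 200 cohorts for noisy trajectory classification, 20 for the
noiseless check, and 500 replicates for interaction-coefficient recovery
(β3 = 1.1, residual noise set so the population R² is 0.639; the mean
*sample* R² at n = 28 is smaller because the log-normal lesion-volume
distribution is heavy-tailed). The determinism check runs the full pipeline
twice on a 20³ grid.

## Known limitations

- Only one model per family is fitted; broader candidate sets (e.g.
  bi-exponential) are out of scope.
- Column-mean imputation ignores dropout mechanisms; no mixed-effects
  longitudinal modelling.
- No permutation or bootstrap significance for voxel loadings or component
  stability; Bonferroni is the only multiplicity control.
- No anatomical labeling of clusters and no registration/segmentation of
  real images: inputs are assumed already aligned on a common grid.
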