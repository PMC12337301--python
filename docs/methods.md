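# Methods

This note documents the statistical models implemented in `epiclock`, the
assumptions behind the synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Data model

The unit of analysis is the **library**: pooled DNA from several individuals
(default 10) of one treatment at one chronological age, bisulfite-converted
and sequenced.  For CpG *i* in library *j* we observe methylated reads
*y<sub>ij</sub>* out of *n<sub>ij</sub>* total.  Counts are authoritative
throughout; methylation percentages in coverage files are never used in a
computation.  A library×site cell with no reads is "no coverage", which is
distinct from an observed 0%.

## Spike-in calibration and methylation-status calling

Bisulfite non-conversion makes a fraction *e* of truly unmethylated cytosines
read as methylated.  *e* is estimated as the pooled ratio methylated/total
over all lambda spike-in sites and libraries (per-library rates are reported
for QC).  Each genomic site is then tested against H₀: "all methylated reads
are non-conversion noise" with a one-sided binomial test at rate *e*;
p-values are BH-corrected across sites and sites with q ≤ 0.05 are retained.

Two pooling modes exist.  The default sums counts over libraries meeting the
coverage floor before testing (one test per site — the powerful choice for
pooled libraries, and the test a pooled binomial model implies); the
alternative tests each library separately and requires significance in at
least `min_samples` libraries.  Defaults — minimum coverage 10, q ≤ 0.05,
`min_samples` = half the libraries — are conventional WGBS settings and are
exposed in the config.  Sites below the coverage floor in every library are
dropped before testing and do not enter the BH family.

## Age-related differential methylation

Per site, (y, n − y) is modelled as binomial with logit link and linear
predictor b₀ + b₁·(age − mean age); significance is the 1-df likelihood-ratio
test against the intercept-only model.  Age is continuous in days (the
downstream clock is continuous in age).  Treatment is not in the default
model — the scan targets age-related loci using all libraries — but
`adjust_treatment=True` adds it, and `treatment_subset` restricts the scan to
one group for sensitivity analysis.

**Overdispersion.**  Pools of individuals vary beyond binomial sampling, and
an unadjusted LRT is anti-conservative (in simulations at intra-class
correlation ρ = 0.02 the realised false-discovery proportion exceeded 0.3 at
a nominal q ≤ 0.05).  The default is therefore a quasi-binomial adjustment
with a **pooled** dispersion: every library is a pool of the same size, so a
common dispersion factor is the natural model.  The per-site Pearson
dispersions are combined by a 10%-trimmed mean across sites (trimming guards
the handful of near-separated fits), floored at 1 so the test is never
deflated, and the LRT is scaled by it.  Per-site dispersion with an
F(1, m−k) reference and the unadjusted test remain selectable
(`dispersion_mode`); the adjustment triggers when the dispersion exceeds a
configurable threshold (default 1).  Sites whose Newton iteration does not
converge (e.g. complete separation) are flagged, excluded from the BH family
and logged, rather than assigned p = 1.

The fits are a batched Newton iteration over all sites simultaneously
(shared design matrix, per-site 2×2 information solves), which makes
replicated whole-matrix scans cheap; agreement with statsmodels' GLM is
asserted in the tests.

## Clock construction

Candidate sites (the significant age-DMLs) are filtered by Pearson
correlation between methylation proportion and chronological age **in control
libraries only**: retain |r| ≥ 0.3 with uncorrected two-sided p ≤ 0.05
(t transform).  Zero-variance sites are excluded with a log entry.

The elastic net uses the glmnet objective
(1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²) with α = 0.5.  Features are
standardised internally and coefficients are reported back on the proportion
scale, so a serialised model is self-contained.  λ runs over 100 log-spaced
values from λ_max (the smallest λ that zeroes all coefficients) down to
10⁻³·λ_max; it is chosen by repeated k-fold cross-validation (default 10
folds × 3 repeats) minimising held-out RMSE, with ties broken toward the
larger (sparser) λ.  The CV unit is the library — pools are the statistical
unit — and folds are age-stratified so no training fold loses age variation;
a degenerate fold triggers a logged refold.  All randomness is seeded.

**Training set.**  The clock is trained on control libraries only and then
applied to the treatment group: the feature filter is defined on controls,
control metrics are honest out-of-fold values, and treatment metrics measure
transfer.  Control validation (R², RMSE) uses out-of-fold predictions at λ*,
averaged over the repeats per library; treatment validation uses direct
predictions from the refit model.  The same convention carries into the
trajectory stage: control libraries enter with their cross-validated
predictions, treatment libraries with direct predictions, so neither group's
slope is inflated by in-sample overfitting.

Prediction requires every nonzero-coefficient ("panel") site to be observed;
`impute="mean"` substitutes training means and is logged.

## Aging-rate (trajectory) statistics

Predicted epigenetic age is regressed by OLS on chronological day, treatment
and their interaction.  Day is centred at the first sampling day for
conditioning; all reported quantities are back-transformed.  With the default
design (40 libraries, 4 parameters) the residual df is 36, asserted in tests.
The interaction estimate is the slope difference; estimated marginal means at
a chosen day use the coefficient covariance for the contrast SE and the
pooled residual df (a single-OLS pooled-variance convention).  No
heteroscedasticity correction is applied by default and the two day-contrasts
are not multiplicity-adjusted (raw post-hoc values are reported).  Percent
slowdown is (1 − s₂/s₁)·100 with a delta-method CI (the ratio −b₃/b₁ of
centred coefficients); the convergence day is the intersection of the two
fitted lines, and it coincides with the day at which the marginal-mean
contrast crosses zero (asserted to 10⁻⁸).

## Survival

Kaplan–Meier per group with Greenwood variance, log-log 95% bands, median =
smallest time with S ≤ 0.5, and median CIs from the band crossings of 0.5
(lifelines).  The Cox treatment effect uses Efron tie handling — daily
survival monitoring guarantees heavy ties — with a two-sided Wald test.  The
hazard translation interprets the treatment HR as acting entirely through a
Δ-day epigenetic-age difference under hazard ∝ exp(β·epigenetic age):
β = −ln(HR)/Δ, and each additional epigenetic day multiplies the hazard by
e^β.  The package deliberately does not fit hazard on per-individual
epigenetic age (pooled libraries provide no per-individual ages).

## Synthetic-data generator

The generator emulates the study design: 2 treatments × 5 timepoints (days
6, 12, 18, 24, 30) × 4 replicate pools of 10 (40 libraries), a minority of
clock CpGs among age-flat null CpGs, and a 1% unmethylated spike-in.

For clock CpG *i* in group *g* at age *a* the latent proportion is
p = expit(b<sub>i</sub> + s<sub>i</sub>·r<sub>g</sub>·(a + o<sub>g</sub>)),
with rate ratio r = 1 and offset o = 0 in the reference group.  The library's
latent ("true epigenetic") age is a\* = r_g·(a + o_g), so reference-group
latent age equals chronological age by construction and the planted rate
ratio maps directly onto the slowdown the trajectory stage estimates.
Defaults: r = 0.708 and o = 2.8 d (the study-scale effect sizes), ρ = 0.02
beta-binomial intra-class correlation (pool-of-10 variability beyond
binomial), one-way conversion error 0.005 (spike-ins measure non-conversion
only; over-conversion has no control and is ignored), negative-binomial
coverage with mean 30 and dispersion 10, floored at one read.

Clock-CpG effect sizes default to slope magnitudes 0.05–0.12 logit/day with
random sign, and the drawn baseline is the logit at the sampling window's
midpoint age, so trajectories traverse intermediate methylation across days
6–30.  Both choices mirror how clock CpGs arise in the real pipeline: they
are *selected* for strong, approximately linear correlation with age over the
sampled window, which excludes saturated sites; baselines drawn independently
of slopes would plant many saturated trajectories that such a selection could
never yield, and would bend the clock's response at the age extremes.  Null
CpGs draw baselines uniformly on ±1.5 logits.

Coordinates are a single artificial contig with 1-based strand-merged
positions (Bismark conventions); the spike-in uses a reserved contig name.
Survival cohorts draw from per-group parametric hazards S(t) = exp(−rate·tᵏ)
(k = 1, exponential, by default; a shared k preserves proportional hazards),
with defaults calibrated to the study's cohorts — control rate ln2/22 (median
22 d), treatment HR 0.35, n = 101 vs 71 — and death times rounded up to whole
days to match daily monitoring and exercise tie handling.  Optional
administrative censoring must be strictly positive (censoring at 0 would
censor every record).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: genomic CpG clustering and co-methylation, per-CpG
dispersion heterogeneity, mapping/coverage biases along the genome,
treatment-specific methylation differences outside clock CpGs, non-linear
age trajectories, and non-proportional hazards (a diapause group whose
median matches the study's under a common exponential family is not
representable; the default reproduces the hazard ratio, not both medians).
Timepoints are adult days post emergence; the diapause larval period itself
is not simulated, and the emergence offset o is deliberately agnostic about
whether it reflects aging during diapause or remodeling at emergence.

## Problem sizes used in validation

The recovery and replicate analyses run the full pipeline on the default
scenario (1,000 CpGs, 40 libraries, 50 planted clock CpGs); the replicated
slope-ordering/CI-coverage analysis uses 100 independent seeds, and survival
CI coverage uses 200 replicates at the study's cohort sizes.  These sizes
give stable Monte-Carlo estimates while keeping a full validation run in the
low minutes on one CPU.

## Known limitations

- The pooled-dispersion quasi-binomial test assumes a common overdispersion
  across sites; strongly heterogeneous dispersion would call for per-site or
  shrinkage estimates (`dispersion_mode="per_site"` exists but is noisier).
- The clock is linear in proportions; saturating CpGs attenuate predictions
  near the age extremes, which compresses fitted trajectories toward the
  mean age and can bias group-slope ratios when groups occupy different
  parts of the age range.
- Median-survival CIs follow the log-log band-crossing convention; other
  conventions (e.g. Brookmeyer–Crowley) differ at small n.
- The hazard translation is an identity, not a fitted model; it assumes the
  entire treatment effect acts through the epigenetic-age difference.
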