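# Methods

This note documents the statistical models implemented in `geoconn`, the
design choices made where the design was genuinely open, and what the
synthetic cohort generator does and does not emulate.

## Connectivity estimation

Each subject contributes a T×K matrix of ICA component time courses (defaults
T = 150 volumes at TR = 2.5 s).  Columns are demeaned and the sample
covariance C uses the 1/(T−1) convention.  Before ridging, C is divided by the
root-mean-square of its diagonal so that a given ridge strength ρ has
comparable effect across subjects with different signal scales (reference
netmat toolboxes apply such a rescaling); a flag disables this for oracle
tests.  The regularized precision is P = (C + ρI)⁻¹ with ρ = 1 by default,
and the partial correlation is r_ij = −p_ij/√(p_ii·p_jj) with the (never
analyzed) diagonal set to 0.  Edges are variance-stabilized with plain
arctanh; no empirical rescaling of Fisher z values is applied (some reference
toolboxes additionally rescale — a documented divergence).  The lower
triangle is flattened in row-major order (2,1),(3,1),(3,2),… so edge position
is comparable across subjects.

Ridge regularization at ρ = 1 shrinks partial correlations toward zero by
roughly a factor of two at these T and K; group *differences* shrink by the
same factor, so standardized effect sizes are approximately preserved.  At
ρ → 0 the estimator equals the closed form from the inverted sample
covariance (tested to 1e−6).

## Group inference

For each edge, an OLS model with the group factor of interest plus sex
(binary indicator) and age at scan (months, uncentered — AIC comparisons are
unaffected by centering) is fit; the omnibus statistic is the partial F
comparing full vs covariate-only models (on the reference design with 4
case-control levels: F(3, 189)).  Effect size is partial η² =
SS_group/(SS_group + SS_resid).  FDR control uses Benjamini–Hochberg across
all analyzed component pairs; pairwise follow-up contrasts within a surviving
edge form their own FDR family.

Pairwise contrasts use **Freedman–Lane permutation**: the edge is
residualized on the covariates under the reduced model, residuals are
permuted and added back to the reduced fit, and the group coefficient is
refit.  This preserves the covariate structure under the null and is the
standard permutation scheme for GLMs.  Tests are two-sided with the add-one
convention p = (1 + #{|t*| ≥ |t|})/(n_perm + 1), so p can never be 0 and its
resolution is 1/(n_perm + 1).  Cohen's d uses the pooled (n−2)-weighted SD
without small-sample correction.

## Model selection

Three designs compete per edge: case-control (all ASD pooled; TD, LD/DD and
TD ASDSib kept as separate levels, never collapsed into one control group),
subtype (ASD split at the 69% fixation cutoff — "69% or more" is inclusive),
and transdiagnostic (continuous % geometric fixation, no group labels).
Subjects lacking eye tracking cannot be stratified and are excluded from the
subtype and transdiagnostic schemes; when schemes are *compared*, those
subjects are dropped from every scheme so all AICs refer to identical data
(comparing AICs across different data sets is a hard error).

AIC uses the full Gaussian log-likelihood with σ² counted as a parameter,
AIC = n·[ln 2π + ln(RSS/n) + 1] + 2(k + 1), matching `lm`-style fits so
absolute values are comparable to numbers produced by standard statistical
environments on the same data.  ΔAIC bands: ≤ 2 "equivalent", [4, 7]
"considerably less support"; the cited rule leaves (2, 4) and > 7 undefined,
so these are labeled "intermediate" and "essentially no support"
respectively.

Cross-validated MAPE uses k = 5 folds, randomly partitioned but stratified by
the finest categorical design label so every group appears in every training
split, sizes differing by ≤ 1, seed-controlled, and the *identical* fold
assignment is reused for every scheme in a comparison (whether the original
analysis stratified or reused folds is unstated; both are configurable).
Held-out actuals of exactly zero make the percentage error undefined and are
excluded with a logged count — with continuous Fisher-z edges this has
probability ~0.  MAPE routinely exceeds 100% when actuals sit near zero,
which is the norm for edges centred close to 0; MAPE differences are reported
in percentage points.

## Brain–behavior association

Within a subtype, ADOS social affect is regressed on [edge, age] by
iteratively reweighted least squares with the Tukey bisquare weight function
(tuning constant 4.685, scale = MAD/0.6745, OLS start, convergence when the
coefficient change < 1e−8, at most 50 iterations; non-convergence is flagged
and the last iterate returned).  The edge coefficient's t statistic is
converted to a partial correlation r = sign(b)·√(t²/(t² + df)) with
df = n − predictors − 1 and no robust df correction (the convention of common
robust-regression toolboxes).  This t-based r is mildly larger in magnitude
than the Pearson analog on clean Gaussian data (≈ +0.03 at |r| = 0.8) because
bisquare weighting trims the residual tails; recovery tests therefore
average over replicates.  Subjects with missing ADOS are dropped per
analysis.

Uncertainty uses the **percentile bootstrap** (the simplest choice consistent
with reporting "95% confidence intervals"): subjects are resampled with
replacement, the robust partial correlation recomputed per resample (a
batched IRLS solves tens of thousands of resamples as stacked linear
algebra; exactly singular resamples fall back to a pseudo-inverse, and
degenerate resamples with constant edge or behavior are redrawn with a
logged count).  Between-subtype differences in correlation strength use the
classical Fisher-z two-sample test; with rounded r = −0.78 (n = 16) vs 0.06
(n = 62) the formula gives |z| ≈ 3.61.

## Power analysis

Analytic power of the two-sided pooled-variance t-test uses the noncentral t
with noncentrality δ = d·√(n₁n₂/(n₁+n₂)) and df = n₁+n₂−2; the minimum
detectable d bisects this curve to |power − target| < 1e−6 (for n = 16 vs 55,
α = 0.05, power = 0.80: d ≈ 0.8071).  The Monte-Carlo check draws both groups
i.i.d. from unit-variance normal laws rather than sampling without
replacement from very large finite populations — at these sample sizes the
two are statistically indistinguishable.

## Motion QC

FD_t sums absolute backward differences of the three translations (mm) plus
the three rotations converted to arc length on a 50 mm sphere (the cited
convention; configurable, with a degrees flag for traces not stored in
radians).  DVARS is the RMS across dimensions of the backward temporal
difference, computed here on component time series since this pipeline
carries no voxel data (a documented divergence from the voxelwise original).
Group balance of mean FD/DVARS uses one-way ANOVA.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes, not
fMRI physics.  Defaults mirror the reference design: group sizes
16/62/31/15/16/55 (total 195), T = 150, TR = 2.5 s, per-group sex counts and
mean FD taken from the design's descriptive table.

* **Time series.**  Planting works on the precision scale: a target partial
  correlation r on edge (i,j) is the off-diagonal −r of a unit-diagonal
  precision matrix, whose partial correlation is then exactly r — the
  generator is its own closed-form oracle (`true_edge_values`).  Positive
  definiteness is enforced by geometric shrinkage of all off-diagonals when
  needed (minimum eigenvalue 0.05).  Temporal structure is AR(1) with
  φ = 0.3 at TR = 2.5 s; innovations carry covariance (1 − φ²)Σ so the
  stationary covariance equals Σ = Θ⁻¹ exactly at any T.
* **Between-subject heterogeneity.**  Each subject's planted edges are
  jittered around the group target with SD 0.2 (typical of the
  between-subject spread of Fisher-z netmat edges), truncated to ±0.9.
* **Default planted effects.**  DMN-OTC: 0.30 in non-ASD groups, 0.18 in
  nonGeo/no-ET ASD, 0.02 in GeoPref ASD (the marked subtype-specific
  deficit); DMN-PVC and DMN-DAN carry uniform ASD reductions.  Values are
  stated on the true partial-correlation scale before ridge shrinkage.
* **Eye tracking.**  Percent geometric fixation is drawn from per-group
  normal laws (GeoPref 80 ± 8, nonGeo 40 ± 14, LD/DD 45 ± 15, TD ASDSib
  30 ± 12, TD 32 ± 12 — placeholders chosen to straddle the cutoff
  plausibly, not estimates of any study's distributions), clamped to
  [0, 100], with rejection sampling so subtype labels are consistent with
  the 69% cutoff.  ASD-noET subjects have no eye-tracking data by
  construction; ADOS is present only for ASD subjects.
* **Behavior coupling.**  For a coupled group, ADOS = μ + b·(e − ē) + ε with
  b calibrated against the realized spread of the group's true edge values so
  the generating correlation equals the target (default −0.78 in GeoPref
  only, residual SD 3.5 on the ADOS scale); scores are clipped at 0.
* **Motion.**  Traces are cumulative sums of Gaussian steps; the step scale
  is set from a subject-level expected mean FD drawn lognormally with the
  group's mean/SD, so group FD distributions match the design's descriptive
  moments and the balance ANOVA behaves realistically.

What the generator does **not** emulate: spatial maps and ICA estimation,
scanner noise spectra and physiological artifact, motion-connectivity
coupling (motion is independent of the signal), non-Gaussian edge
distributions, and missingness beyond the no-eye-tracking pattern.  Passing
recovery tests therefore demonstrates the statistical machinery is correct
under the model's assumptions, not that those assumptions hold in real rsfMRI
data.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible;
`run_all` spawns per-stage substreams from one global seed so stages are
reproducible independently of execution order.  The test suite runs its
heavier property checks at deliberately chosen sizes: permutation type-I
error over 1,000 null simulations at n_perm = 500; AIC model recovery over
50 replicate cohorts at the full 195-subject design with K = 4 labeled
components (the planted GeoPref deficit corresponds to a standardized gap of
≈ 0.9 on the estimated-edge scale); brain–behavior recovery over 20
replicate cohorts with 1,000-resample bootstraps; bootstrap coverage over
200 replicate datasets at n = 100 with 5,000 resamples.

## Known limitations

* The ridge estimator at ρ = 1 is biased toward zero by design; reported
  group means are not estimates of the true partial correlations (the ρ → 0
  configuration is, for well-conditioned data).
* The t-to-r conversion from the robust fit slightly overstates |r| relative
  to Pearson on clean data (see above).
* The permutation scheme assumes exchangeability of covariate-adjusted
  residuals; heteroscedastic groups can perturb its nominal level slightly.
* AIC comparisons assume Gaussian residuals; heavy-tailed edges would favor
  a robust criterion that is out of scope here.
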