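# Methods

## Problem and model

Gestational diabetes mellitus (GDM) is diagnosed at 24–28 weeks of
gestation; clinically useful prediction has to happen earlier. `gdmlda`
implements a screening analysis that uses four routine complete-blood-count
biomarkers — hemoglobin (Hb, g/dL), hematocrit (Hct, %), fasting blood
sugar (FBS, mg/dL) and red blood cell count (RBC, ×10¹²/L) — measured at
two prenatal visits (first trimester and weeks 16–20) to allocate each
woman to the non-GDM (population 1) or GDM (population 2) group before the
diagnostic window.

Subject *i*'s responses are stacked into `y_i` of length q = 2p (p
biomarkers × 2 visits, visits nested within biomarker) and modelled as a
multivariate longitudinal linear mixed model

    y_i = X_i β + Z_i b_i + ε_i,    b_i ~ N(0, D),    ε_i ~ N(0, Ω)

* **Mean structure.** Seemingly-unrelated-regressions layout: every
  covariate gets a biomarker-specific coefficient (the responses live on
  incommensurate scales, so shared coefficients would be meaningless).
  Per-biomarker terms: intercept, GDM indicator (0/1), visit indicator
  (0/1), maternal age, and visit-specific BMI, SBP, DBP. A group×visit
  interaction is available behind a flag and off by default (in data of
  this kind the interactions are routinely non-significant, and the
  default keeps the discriminant's group contrast a single coefficient
  per biomarker).
* **Random structure.** One random intercept per biomarker with
  unstructured p×p covariance `D` (`Z_i = I_p ⊗ 1_2`). With only two
  visits this is the richest identifiable structure; random slopes are
  not identifiable and are excluded.
* **Residual structure.** Diagonal, biomarker-specific variances
  (`Ω = diag(σ²_m) ⊗ I_2`); all cross-biomarker and cross-visit
  dependence is carried by `D`. A Kronecker (biomarker × time) residual
  structure was considered and rejected: with t = 2 and an unstructured
  `D` it is only weakly identified, and fits would trade the same
  covariance mass between `D` and `Ω`.

**Estimation** is direct maximum likelihood (not REML — the discriminant
rule and the likelihood oracle both use the ML objective). `β` is profiled
out by GLS for every covariance-parameter vector θ (log-Cholesky
parameterization of `D`, log residual variances, so `D ⪰ 0` and `σ² > 0`
by construction), and the profile likelihood is maximized by L-BFGS-B
with numerical gradients (`ftol` 1e-11, `gtol` 1e-7; a stalled line
search is retried once with a coarser finite-difference step).
Non-convergence is never silent: the results object carries
`converged=False` plus the optimizer message, and a warning is emitted.
Because the design is balanced, the marginal covariance
`V = Z D Z' + Ω` is common to all subjects and the profile likelihood
depends on the data only through second-moment matrices accumulated once,
making each evaluation O(q²k²) independent of n; a 4-marker fit at
n = 2000 takes well under a second on one core.

## Allocation rule

With fitted parameters, subject *i* is scored by the equal-covariance
Gaussian linear discriminant

    L_i = (μ_1i − μ_2i)' V⁻¹ (y_i − ½(μ_1i + μ_2i))

where `μ_gi = X_i^(g) β̂` is the model mean with the group indicator forced
to g and all other covariates at the subject's observed values. The
subject is allocated to non-GDM iff `L_i ≥ ln(π₂/π₁)`; a score exactly at
the threshold stays in population 1 (the rule's "≥"). This is exactly the
Bayes rule for two Gaussian populations with common covariance and priors
(π₁, π₂); the package verifies the equivalence against a brute-force
density-comparison classifier in its acceptance suite. Priors default to
the fitted sample's group proportions and are overridable. Posterior
probabilities come from the same quantities in log space
(`p₁/p₂ = e^L · π₁/π₂`).

The *univariate strategy* is the identical machinery with a single-marker
model (q = 2); the *multivariate strategy* uses all four markers (q = 8).

## Evaluation

The ROC positive class is GDM and the risk marker is the **negated**
discriminant score (the score is oriented toward non-GDM); this is fixed
internally so a sign error cannot silently report 1−AUC. AUC is the
Mann–Whitney estimator (ties ½), identical to the trapezoidal area under
the exhaustive-threshold empirical curve. Confidence intervals: DeLong
structural-components normal approximation (default, truncated to [0,1])
or a stratified percentile bootstrap (2000 resamples, seeded). Two named
operating points are reported, because screening studies rarely state
their threshold: **bayes** (`ln(π₂/π₁)`, the allocation rule's own
threshold — with π₂ ≈ 0.08 it is highly specific and insensitive) and
**youden** (maximizes sens + spec − 1, ties to the lower threshold).
Reports render percentages with round-half-up only in the presentation
layer; all stored values keep full precision.

Both **resubstitution** and **stratified k-fold cross-validation**
(default k = 10, seeded, priors re-estimated per training split) are
computed and labelled. Resubstitution is optimistic: under a zero group
effect at n = 600 with 8% prevalence the resubstitution multivariate AUC
sits around 0.64 purely from evaluating 28 fitted coefficients on their
own training data, while the cross-validated AUC is correctly centered at
0.5. Null-calibration checks therefore use the out-of-fold estimate.

## Screening (diagnosis) rule

The label-generating outcome is the two-step diagnosis: a 50-g GLT with
1-h plasma glucose ≥ 140 mg/dL (inclusive) triggers a 100-g OGTT, judged
by Carpenter & Coustan: GDM iff at least two of fasting ≥ 95, 1-h ≥ 180,
2-h ≥ 155, 3-h ≥ 140 mg/dL. All thresholds inclusive; mg/dL only. The
implementation is verified exhaustively on the ±1 mg/dL boundary grid,
including monotonicity (raising any glucose value never revokes a
positive call).

## Synthetic cohort generator

The reference cohort (600 pregnant women, 49 GDM = 8.2%) is not publicly
deposited, so the generator emulates it from its published summary
statistics:

* **Label-first:** group ~ Bernoulli(0.082), then biomarkers drawn from a
  group-conditional 8-dimensional normal whose means/SDs are the published
  group × visit values. The generator's class-conditional moments are
  therefore exactly the calibration targets. (An OGTT-consistency layer
  can synthesize glucose panels matching the labels, for exercising the
  diagnosis rule.)
* **Correlations are assumptions, not data.** The summaries print no
  correlations. Defaults: corr(Hb, Hct) = 0.65, corr(RBC, Hb) =
  corr(RBC, Hct) = 0.45, corr(FBS, hematologic) = 0.10, and 0.5 between
  the two visits of the same marker, combined as `R ⊗ [[1, ρ], [ρ, 1]]`
  (positive definite whenever R is and |ρ| < 1). These are
  physiologically plausible and fully configurable; the multivariate AUC
  depends on them, so downstream performance numbers characterize *this
  synthetic regime*, not the original cohort.
* **One typo correction:** the published non-GDM visit-1 RBC dispersion
  (5.01 for a mean of 4.39 ×10¹²/L) is physiologically impossible and is
  replaced by 0.51.
* Covariates (age; visit-specific BMI/SBP/DBP; parity; education) follow
  the published group-wise summaries; only age/BMI/SBP/DBP enter the
  design matrix, parity and education exist for descriptive tables.

A second generator, `generate_from_model`, simulates exactly from the
mixed model with known (β, D, Ω) and is the basis of the
parameter-recovery studies.

What passing tests on this synthetic cohort do **not** show: performance
on real cohorts (real biomarker correlations, non-normal tails,
measurement error, attrition and incomplete visits are all absent), and
the generator draws biomarkers conditional on the label rather than
modelling the biological path from glycemia to the label.

## Descriptive statistics

Categorical characteristics: Pearson chi-square without continuity
correction (a Yates flag exists). Continuous: pooled-variance Student
t-test by default, Welch behind a flag. Repeated biomarkers: two-way
mixed-design ANOVA (between = group, within = visit), implemented from
its sums-of-squares decomposition; with two within-levels the design is
equivalent to a one-way ANOVA on per-subject means (group) and on visit
differences (time, interaction), which remains valid for unbalanced
groups and needs no sphericity correction. The implementation is checked
against an explicit cell-means decomposition and against `pingouin` on
simulated data.

## Numerical and design choices

* Stacking order is visits-within-biomarker everywhere; all covariance
  assembly and the score respect it.
* Group coding is fixed at 1 = non-GDM, 2 = GDM (population indexing of
  the allocation rule); the design matrix uses a 0/1 indicator.
* Complete-case policy: subjects missing a visit are dropped with a
  logged count; the cohort validator reports (never raises on) every
  invariant violation.
* Degenerate inputs: single-class score vectors, zero-marginal
  contingency tables, non-PD covariances and rank-deficient designs all
  raise typed errors naming the offending columns/parameters.
* Determinism: every stochastic component takes an explicit seed;
  a pipeline config (hashed into the report's provenance block) fully
  determines every reported number byte-for-byte.

## Problem sizes used in the checks

Monte-Carlo checks use sizes chosen to put estimator noise well below the
asserted tolerances: moment fidelity at n = 200 000 (averaged over five
cohorts), recovery at n = 2000 over 1200 model-exact replicates (bias
bound 0.1 of the per-component Monte-Carlo SD), D-consistency contrasted
between n = 500 and n = 2000, null calibration of the descriptive tests
over 2000 replicates, information pooling averaged over 10 cohorts of
n = 5000, and the binormal limit at 20 000 observations.

## Known limitations

* Two visits and two groups only; no unbalanced visit schedules, no GEE
  or Bayesian estimation, no quadratic discriminant (group-specific V).
* The DeLong interval is asymptotic; with 49 positives it is serviceable
  but the bootstrap option is the safer choice near AUC extremes.
* Univariate AUCs on the synthetic defaults differ from the reference
  cohort's published ones (notably FBS, whose published visit-2 group gap
  is large); this is a property of simulating from printed moments with
  assumed correlations, not a target the generator tunes toward.
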