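# Methods

## Scope and data model

`polypattern` implements a biomarker-pattern discovery pipeline for 24-h
urinary polyphenol excretions and food-group intakes, together with a
synthetic cohort generator that provides ground truth. The in-memory
containers are:

- `MetaboliteMatrix` — subjects × metabolites excretions with a below-LOQ
  mask, per-metabolite LOQ, missingness mask, and center/batch labels. A
  `stage` tag (`raw → censor-handled → logged → imputed → residualized`)
  is stamped by each transform; transforms refuse out-of-order input.
- `IntakeTable` — subjects × food groups for one instrument (24-HDR or DQ)
  with per-subject energy. The raw g/day matrix is always retained;
  consumer status is *derived* as raw intake > 0, never stored separately.
- `CovariateSet` — sex (binary), BMI (kg/m²), age (years).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, in
the simplest form that makes every downstream estimand available in closed
form — a linear-Gaussian model on the log scale:

1. Consumption: subject i consumes food f with probability `consumer_prev_f`
   (defaults: citrus 38.9%, apple & pear 47.6%, olives 9.3%, coffee 86.3%,
   tea 24.6%, all wine 41.9%, red wine 25.5%). Intake among consumers is
   log-normal (`intake_logmean`, `intake_logsd`, log g/day; defaults are
   round numbers typical of European adult cohorts, e.g. coffee
   `exp(6.0) ≈ 400 g/day`); non-consumers report exactly 0 on the 24-HDR.
2. Habitual signal: `z_f` = cohort-standardized `log1p` of the 24-HDR
   intake. Non-consumers enter at `z = (0 − mean)/sd`: non-consumption
   itself carries signal, so consumers and non-consumers are discriminable
   by loaded metabolites — a prerequisite for the AUC evaluation to be
   meaningful.
3. Metabolites: `log m_ij = μ_j + Σ_f Λ_fj z_if + center_i + batch_i +
   ε_ij`, `ε_ij ~ N(0, noise_sd_j²)` (default SD 1.0 on the log scale).
   Center (8) and batch (10) labels are balanced random allocations with
   additive `N(0, 0.5²)` and `N(0, 0.3²)` log-scale shifts — sizable, to
   mimic multi-center, multi-batch laboratory data.
4. DQ: `u_f = a·z_f + sqrt(1−a²)·N(0,1)` with `a = dq_attenuation`
   (default 0.5), mapped back to g/day through the 24-HDR `log1p` moments.
   The DQ is thus a noisy, attenuated proxy of the signal driving the
   metabolites, reproducing the expectation that questionnaire-based
   (habitual) performance is weaker than recall-based (acute) performance.
   The attenuation value is a free parameter of the generator, not an
   estimate of any real instrument's error.
5. Censoring and missingness, applied after the abundances are drawn:
   each metabolite's LOQ is set at its `loq_quantile` empirical quantile
   (default 2%; three panel members — procyanidins B1/B2 and
   (+)-gallocatechin — default to 99% so the censoring-exclusion rule is
   exercised); values are missing at random at `missing_rate` (default 5%).
   Missing wins over censored when both are drawn.
6. Covariates sex/BMI/age/energy are independent of diet (defaults: 41.7%
   men; age 53.9 ± 8.5 y; BMI 26.0 ± 4.3 kg/m²; energy 2200 ± 785 kcal/d).

### Calibration

For a single loaded pair, `corr(log m, z) = λ/sqrt(λ² + σ²)`, so
`loading_for_target_correlation(ρ, σ) = ρσ/sqrt(1−ρ²)` injects an exact
population correlation. When a metabolite loads on several foods the
loadings are calibrated jointly, `λ_f = ρ_f σ/sqrt(1 − Σ_f ρ_f²)`, which
keeps every marginal correlation at its target under independent food
signals. The default loading matrix calibrates the full observed 34 × 7
food–metabolite correlation table (including weak and negative cells), so
default cohorts reproduce a realistic cross-correlation structure: strong
foods (red wine, coffee, citrus) pass the polyphenol-rich screen
essentially always, while borderline foods (tea, whose best correlation
sits at the 0.3 threshold) pass in only part of the seeds — as a borderline
food should.

### What the generator does *not* model

No pharmacokinetics, gut-microbial conversion, within-person day-to-day
variation, seasonality, or correlated food-consumption patterns (food
signals are independent); DQ and 24-HDR share a single habitual signal
rather than a time-lag structure. Passing tests therefore demonstrate the
statistical machinery under the assumed linear-Gaussian structure, not
performance on real cohort data.

## Preprocessing

- Below-LOQ values are replaced by LOQ/2 (censored ≠ missing; replacement
  happens before imputation). Metabolites with ≥ 98% of observed values
  below LOQ are excluded (strict ≥, so 97.9% is retained).
- Natural log throughout; intakes use `log(x + 1)` with the offset fixed at
  1 g/day so zero intakes map to zero and consumers' ordering is preserved.
  Downstream statistics are scale-invariant, so the base is a convention.
- Missing log-abundances are imputed by multivariate-normal EM. Rows are
  grouped by missingness pattern; the M-step covariance includes the
  conditional-covariance correction plus a ridge of `1e-8·tr(Σ)/p` on the
  diagonal for stability. Convergence is declared when the largest absolute
  change in mean or covariance falls below `tol` (default 1e-6, cap 500
  iterations; non-convergence raises, carrying the last change). Missing
  entries are filled with their conditional expectations at the converged
  parameters; observed entries are preserved exactly.
- Center and batch enter one GLM jointly as two dummy-encoded unordered
  factors; metabolite residuals from that model are the analysis values.
  Intakes are residualized on untransformed energy. Residualization checks
  design rank and names aliased columns on failure; residual column means
  are zero to 1e-10 and residualization is idempotent.

## Screening and preselection

Partial Pearson correlations condition on sex, BMI and age by residualizing
both variables on `[1, Z]`; p-values use `t = r·sqrt(df/(1−r²))`,
`df = n − 2 − |Z|`, two-sided. The preselection rule — ≥ 5 significant
metabolites and max r ≥ 0.3 — counts *positive* correlations only
(biomarker candidates are excretions that rise with intake) and compares
the signed r against the 0.3 floor. No multiple-testing correction is
applied in the screen; this is deliberate fidelity to the screening design
and a known limitation.

## Reduced rank regression and VIP

X and Y are standardized to unit variance before fitting, making weights
and VIP scale-free. The rank-K solution is `B_K = B_OLS V_K V_Kᵀ`, `V_K`
the top-K eigenvectors of `Ŷᵀ Ŷ`; factor weights are the unit-normalized
columns of `B_OLS V_K`. Eigen-ties break by column index; each weight
vector is oriented so its largest-magnitude entry is positive (deterministic
output). Zero-variance predictors and near-singular `XᵀX` (condition
number > 1e12) raise named errors. `explained_share_k = λ_k / ΣᵢΣⱼ Ys²`;
for q = 1 this equals the OLS R², and the rank-1 score correlates ±1 with
the OLS fitted values — both serve as oracle checks in the tests.

`VIP_j = sqrt(p · Σ_k R²_k w_jk² / Σ_k R²_k)` with `‖w_k‖ = 1`, giving the
normalization `Σ_j VIP_j² = p` exactly. With univariate responses the
pipeline rank is always 1, so selection uses `VIP_j = sqrt(p)·|w_j|`.

## Selection

RRR-VIP keeps VIP strictly greater than 0.85 (a VIP exactly at the
threshold is excluded). LASSO standardizes predictors (ddof = 1), leaves
the intercept unpenalized, solves the path via coordinate descent
(scikit-learn), and picks the penalty minimizing mean 5-fold CV squared
error over seeded random folds; the one-standard-error rule is available
(`rule="1se"`) but the CV minimum is the default, as the most literal
reading of penalty choice by cross-validation. Coefficients are reported on
the standardized scale, sorted descending (signed); VIP selections sort
descending by VIP.

## Evaluation

`split_two_fold` draws uniformly random disjoint halves (|test| =
floor(n/2); a fixed test size is available for unequal historical splits).
A rank-1 pattern is fitted on the training half only — weights,
standardization vectors, and the single-biomarker comparator (highest
positive training-fold partial correlation; ties to the lower column index)
never see test subjects. The test score is oriented by the sign of its
training-fold correlation with intake, since the weight-sign convention is
about reproducibility, not direction. Preprocessing (center/batch and
energy residualization, EM) runs once on the full cohort before splitting —
mirroring how such analyses are run in practice, and a mild, documented
leakage.

The covariate-adjusted AUC fits `consumer ~ score + sex + BMI + age` by
logistic regression and takes the ROC AUC of the linear predictor, with a
95% CI from the DeLong variance estimator. The linear predictor is
**cross-fitted** by default (deterministic stratified folds; coefficients
estimated out of fold): fitting the four coefficients on the same subjects
whose AUC is computed inflates the null AUC well above 0.5 at realistic
fold sizes (≈ 0.57 at n = 237 in our measurements), and cross-fitting
removes that optimism while keeping the logistic adjustment — so an
uninformative score yields AUC centered at 0.5, as a calibrated evaluation
statistic must. The in-sample variant remains available
(`cross_fit=False`). A covariate-only baseline AUC is reported alongside so
the score's increment over demographics is visible. Under complete
separation the (non-converged) predictor's ranking is still used and the
row is flagged. AUC on the ranking of a score is invariant to strictly
monotone transforms of it.

## Pipeline, seeding, formats

`run_pipeline` executes preprocess → screen → preselect → select (both
methods) → split → evaluate → report, persisting each stage (correlation
matrices, selection lists, the evaluation report as CSV; a JSON results
bundle). One global seed expands into independent per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, so stages can be rerun in
isolation reproducibly; identical config + seed gives byte-identical
outputs. Cohorts on disk are plain CSV (empty cell = missing; LOQ sidecar;
the below-LOQ mask is reconstructed as value < LOQ) plus `truth.json` for
synthetic cohorts. Threshold defaults live in `PipelineConfig`: alpha 0.05,
≥ 5 significant, r ≥ 0.3, VIP > 0.85, 5 LASSO folds, equal split, 98%
exclusion, intake offset 1 g/day.

## Problem sizes used in the test suite

Monte-Carlo checks run at the cohort scale the method targets (n = 475 for
recovery and selection checks; 20–100 seeds) and at reduced sizes
(n = 200–300, 50 seeds) for null-calibration and cross-validation-direction
properties, where the estimands are size-free. `scripts/acceptance.py`
re-estimates the four flagship injected correlations at n = 475 over 20
seeds each.

## Known limitations

- The evaluation's two-fold split is a single random split, not repeated
  CV; per-seed variability of test-fold metrics is therefore substantial at
  n ≈ 475 (CIs in the report quantify only the AUC's sampling noise within
  the fold).
- The screen's significance counting is uncorrected for multiplicity.
- EM assumes joint normality of log-abundances and missingness at random;
  informative missingness (e.g., missing because below detection) should be
  handled as censoring, not missingness.
- Rare foods (consumer prevalence ~10%) can produce test folds with very
  few consumers; the DQ mapping can push high-prevalence foods to a single
  class in a fold, in which case that row is skipped with a warning.
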