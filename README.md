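# polypattern

Discovery and validation of **urinary polyphenol biomarker patterns** for
dietary intake assessment.

Nutritional epidemiology needs objective markers of what people actually
eat. Single urinary metabolites (hesperetin for citrus, caffeic acid for
coffee, gallic acid ethyl ester for red wine, ...) are useful but limited:
foods release many polyphenols, metabolites are inter-correlated, and some
are too weak alone to discriminate consumers from non-consumers.
`polypattern` implements a pattern-based alternative: it selects an optimal
subset of 24-h urinary polyphenol excretions per polyphenol-rich food group
and combines them into a single score that maximizes the explained variance
of intake, then evaluates that score out of sample.

The package is aimed at biostatisticians and nutritional epidemiologists
working with targeted urinary metabolomics plus dietary-recall data, and at
methodologists who want a fully synthetic, ground-truth-controlled testbed
for biomarker-pattern algorithms.

## The method

Given excretions `X` (subjects × metabolites, μmol/24 h) and food intakes
`y` (g/day, from a 24-h dietary recall, 24-HDR, or a habitual dietary
questionnaire, DQ):

1. **Preprocessing** — below-LOQ values → LOQ/2; metabolites ≥ 98% censored
   excluded; natural log; missing values imputed by multivariate-normal EM;
   center and laboratory-batch effects removed by GLM residuals. Intakes:
   `log(x+1)`, energy-adjusted by GLM residuals.
2. **Screening** — partial Pearson correlations `r(metabolite, food | sex,
   BMI, age)`; a food group is *polyphenol-rich* if ≥ 5 metabolites are
   significantly positively correlated (p < 0.05) and at least one r ≥ 0.3.
3. **Selection** — per food, two methods: **RRR-VIP** (rank-1 reduced rank
   regression on all metabolites; keep VIP > 0.85, where
   `VIP_j = sqrt(p · Σ_k R²_k w_jk² / Σ_k R²_k)` with unit-norm factor
   weights `w_k`, so `Σ_j VIP_j² = p`) and **LASSO** (L1 path, penalty by
   5-fold cross-validation; keep nonzero coefficients).
4. **Patterns** — reduced rank regression of intake on the selected
   metabolites: after standardization, `B_K = B_OLS V_K V_Kᵀ` with `V_K` the
   top eigenvectors of `Ŷᵀ Ŷ`; with one food (q = 1) the rank-1 score
   direction coincides with the OLS prediction direction.
5. **Evaluation** — two-fold cross-validation: fit weights on a random half,
   score the held-out half; report the partial Pearson r of score with
   intake (given sex, BMI, age) and the consumer/non-consumer ROC AUC
   adjusted for the same covariates via logistic regression, with a DeLong
   95% CI — per instrument (24-HDR and DQ) and against a best
   single-metabolite comparator.

Because matched cohort data of this kind are not publicly deposited, the
package ships a first-class **synthetic cohort generator**
(`polypattern.synthetic`): zero-inflated consumption, log-normal intakes,
metabolite log-abundances linearly loaded on standardized log-intake
signals, center/batch shifts, LOQ censoring, missing-at-random values, and
an attenuated DQ proxy. Loadings are calibrated so any target correlation
can be injected exactly (`loading_for_target_correlation`), which makes
every pipeline stage testable against ground truth.

## Worked example

```python
import polypattern as pp

cohort = pp.generate_cohort(pp.GeneratorConfig(n_subjects=475, seed=7))
bundle = pp.run_on_cohort(cohort, pp.PipelineConfig(seed=7))
print(bundle["preselected_foods"])
rep = bundle["report"]
print(rep[(rep.food == "Red wine") & (rep.instrument == "24-HDR")])
```

prints (abridged):

```
['Citrus fruits', 'Olives', 'Coffee', 'Tea', 'All wine', 'Red wine']
    food          method              comparator  ...     r  auc_pct  auc_ci_lo_pct  auc_ci_hi_pct
Red wine       single-PP Gallic acid ethyl ester  ... 0.666     92.3           88.3           96.3
Red wine RRR-VIP-pattern                          ... 0.705     93.0           88.6           97.4
Red wine   LASSO-pattern                          ... 0.715     93.9           89.9           97.8
```

Six food groups pass the polyphenol-rich screen on this cohort. For red
wine, the single best biomarker (gallic acid ethyl ester) ranks held-out
subjects by intake at r = 0.666 and separates consumers from non-consumers
with a covariate-adjusted AUC of 92.3% (95% CI 88.3–96.3); the RRR-VIP
pattern (3 metabolites, led by gallic acid ethyl ester with VIP 4.64) and
the LASSO pattern do slightly better — the qualitative signature the method
is designed to show. DQ rows of the same report are systematically weaker,
reflecting the generator's attenuated habitual-intake proxy.

The same pipeline is scriptable from a shell:

```sh
polypattern simulate --seed 7 --n 475 --out cohort/
polypattern run --cohort cohort/ --seed 7 --out results/
```

which persists the correlation matrices, the per-food selection lists, and
the evaluation report as CSV plus a JSON bundle.

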