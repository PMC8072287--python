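# Methods

This note documents the statistical procedures implemented in `cytoratio`,
the synthetic generative law used to test them, the numerical choices, and
the design decisions taken where the problem was genuinely open.

## Data model

A cohort is one row per patient: 27 plasma cytokine concentrations
(pg/mL; Bio-Plex-style 27-plex panel) at timepoints S0 (baseline), S1
(weeks 4–6) and S2 (weeks 10–12), a best-overall-response category, PFS
and OS in days with event indicators, and a discovery/validation tag.
Endpoints: R/NR (R = CR, PR or SD; NR = PD) and CB/NCB (CB = PFS strictly
greater than 180 days; a PFS of exactly 180 is NCB).

**Feature construction.** 162 log2-scale candidates: 27 × 3 levels
`log2(x + pc)` and 27 × 3 ratios as differences of log2 levels, so
`c@S1/S0 + c@S2/S1 = c@S2/S0` holds by construction. The pseudocount `pc`
is per-cytokine: 0 when the cytokine has no zeros, half its smallest
positive observed value otherwise (configurable; the values used are
recorded in the matrix provenance and reapplied verbatim when frozen
artifacts are validated on a new cohort). Missing timepoints yield missing
entries in the affected columns only; analyses are complete-case, never
imputed.

## Differential screen

Each feature is compared between endpoint groups with a two-sided
Wilcoxon rank-sum test. The exact mode enumerates the full rank-sum
distribution by a subset-sum dynamic program over doubled midranks (ties
handled exactly); two-sided p = min(1, 2·min(P(W≤w), P(W≥w))). The
approximate mode is the normal approximation with tie correction and a
0.5 continuity correction; `auto` uses the exact distribution for
tie-free pooled samples of at most 12. The approximation tracks the exact
p within a few percent for p ≥ 0.05 at n = 20 but overstates extreme
tails (an order of magnitude at p ~ 1e-5), which is intrinsic to normal
tail approximation.

Fold changes are group-1-over-group-0 central values on the anti-log
scale; the default central value is the median (consistent with the
rank-based test; the log2 fold change of medians is then the difference of
log2 medians), configurable to the mean. Significance is
|log2 FC| > 1.0 and −log10 p > 1.3 on raw p-values — no multiplicity
correction, matching the screening convention; a Benjamini–Hochberg
q-value column is emitted for reference and never alters the flag.

## Classical models

Written from first principles so their behavior is fully specified:

* **Logistic regression** by Newton/IRLS with step-halving; convergence
  when the relative penalized log-likelihood change is below 1e-10 (cap
  100 iterations). Wald standard errors come from the observed
  information. Perfect separation of the fitted linear predictor (with no
  penalty) is detected and reported as non-convergence — never silently
  returned. An optional ridge penalty `alpha/2·||β||²` (slopes only)
  regularizes degenerate or separated designs.
* **AIC** = 2k − 2·logLik with k counting the intercept. Stepwise search
  is greedy (forward, or forward–backward with `direction="both"`); a
  move is accepted only on a strict AIC decrease, ties broken by input
  order, so the search is deterministic.
* **LDA** with pooled covariance and class-count priors; classification
  thresholds the discriminant axis `Σ⁻¹(μ₁−μ₀)`. A singular pooled
  covariance triggers a diagonal ridge fallback with a warning. Error
  rates are apparent (resubstitution) by default — the standard
  discriminant-analysis report — with cross-validation available through
  the generic CV utility.
* **AUC** is the rank-based (Mann–Whitney) definition, ties at half
  credit. The ROC module recomputes it independently as the trapezoid
  over the threshold-scan polygon; the two agree to machine precision and
  are tested against an O(n²) pairwise enumeration.
* **Cross-validated AUC**: stratified k-fold (default 5, i.e. 80/20),
  seed-determined partition; stratification is the default because a
  ~28% minority class in a 67-patient cohort otherwise yields single-class
  folds, which are skipped with a warning and recorded.

## Joint factor screening

Forward selection of a logistic model on the training cohort, gated on
both cohorts. Per step:

1. every remaining candidate is refit (training cohort, ridge-stabilized
   logistic, default `ridge = 1.0`) and ranked by the **objective** —
   default the training log-likelihood, the classical stepwise criterion;
   AUC-based objectives (`sum`, `min`, `validation`, `train`) are
   configurable;
2. the top candidate is accepted iff (a) every slope coefficient is
   Wald-significant at α = 0.05 and (b) the **evaluation function**
   improves by more than k = 2 per included factor. The default
   evaluation function is the validation-cohort deviance (−2·logLik of
   the training-fitted model scored on the held-out cohort), compared
   cumulatively against the intercept-only model: with j factors included
   the cumulative improvement must exceed k·j. A training-AIC evaluation
   (per-step improvement > k) is available instead;
3. the loop halts when the top candidate fails a gate or `max_factors`
   is reached. Both AUCs are recorded at every step, so the audit trace
   doubles as the selection report (AUCs on the 0–100 scale; the
   evaluation-function column decreases as factors are added).

Design rationale, since the evaluation function and the precise dual-set
rule are the open design points of this procedure:

* An out-of-sample evaluation gate is what makes the procedure honest
  with 162 candidates: training-side gates (Wald, AIC) are passed almost
  surely by the best of 162 noise candidates (winner's-curse selection),
  whereas the validation deviance of a noise factor is independent of its
  training rank. Measured on effect-free synthetic cohorts, the default
  configuration selects ≥ 2 factors in about 1% of runs; replacing the
  gate with a training-AIC rule inflates that to ~25%.
* Ranking by training likelihood (not by validation performance) keeps
  the gate unbiased: any validation-aware ranking re-introduces selection
  bias into the very quantity being gated.
* The per-factor cumulative form of the gate (k·j) behaves like an AIC
  penalty applied to the validation deviance: each retained factor must
  keep paying for itself out of sample, but a genuinely strong second
  factor is not rejected for a single noisy per-step increment.
* The ridge stabilization matters at realistic effect sizes: a strong
  two-factor model on 67 patients approaches separation, where
  maximum-likelihood Wald statistics collapse (Hauck–Donner effect) and
  would veto exactly the best models. The ridge bounds the coefficients;
  with `alpha = 1` on log2-scale features the fit is within numerical
  noise of the MLE for moderate models.

## Ratio biomarker

A two-feature logistic model with opposite-sign coefficients
(β₁ > 0 > β₂ on log2 features) motivates the single factor
numerator/denominator; on the log2 scale the score is the column
difference, a strictly increasing function of the raw ratio. The collapse
preserves patient ranking — hence AUC — exactly iff |β₁| = |β₂|; it is
performed for any opposite-sign pair, always accompanied by a fidelity
report (ΔAUC between model linear predictor and ratio score, computed by
the rank definition, plus a DeLong paired test), and warns when |ΔAUC|
exceeds 0.01. Same-sign or >2-feature models are refused. Cutoffs are
derived on the log2 score and reported on the raw ratio scale
(`2**cutoff`), alongside the equivalent probability-scale threshold of
the logistic model.

## Survival layer

* **ROC / Youden**: thresholds at midpoints between adjacent distinct
  scores with ±∞ sentinels, predicted-positive meaning score > t; the
  optimum maximizes sensitivity + specificity − 1, ties resolved toward
  higher sensitivity. Degenerate all-tied scores return the −∞ sentinel
  with a warning.
* **Dichotomization** is strict (high iff score > cutoff), mirroring the
  strict PFS > 180 convention.
* **Kaplan–Meier**: product-limit estimator stepping at event times with
  Greenwood variance and log(−log) 95% bands (hand-written; cross-checked
  against lifelines in tests).
* **Log-rank**: two-group observed-minus-expected with hypergeometric
  variance across event times, 1-df chi-square.
* **Hazard ratio**: univariate Cox partial likelihood on the group
  indicator with Efron tie handling (via lifelines). All events in one
  group ⇒ monotone likelihood; the HR is reported as unbounded (0 or ∞)
  with the corresponding CI endpoint, never as a finite estimate.
* **Subgroups** (histology, PD-1 drug) re-run the identical stratification
  on the subset, warning below 10 patients per biomarker group.

CIs are 95%, tests two-sided, α = 0.05 throughout.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes —
it is a test harness, not an estimate of any real study.

* **Cohorts**: 67 discovery + 24 validation patients with responder
  counts fixed at the expected composition (19/67 ≈ 28.4%; 7/24),
  mirroring an observed enrolment rather than a binomial draw.
* **Dual-hit response model**: objective response requires both marker
  events — an IP-10 rise (immune activation) and an IL-8 fall (tumor
  burden reduction). 10% of patients per marker are exclusive partial
  hits: one marker shifts without radiographic response. Partial hits
  keep each marker informative conditional on the other (the reason a
  two-marker panel beats either alone) and prevent the two-factor model
  from perfectly separating the classes.
* **Cytokine levels**: log-normal around plausible plasma medians
  (e.g. IP-10 500 pg/mL, IL-8 15 pg/mL, RANTES 5000 pg/mL), with a
  patient factor shared across cytokines (exchangeable ρ = 0.2), a
  stable patient-by-cytokine baseline (log2 SD 1.3 — cytokines span
  orders of magnitude between patients), and per-timepoint noise of
  log2 SD 0.2 (multiplex assays reproduce at roughly 15% CV), inflated
  1.5× at S1, the most volatile mid-chemotherapy draw. A hit multiplies
  S2 by the planted effect (IP-10 ×2.0, IL-8 ×0.5) and S1 by the half
  log-effect (×√2, ×1/√2): the change is partially developed by weeks
  4–6. These choices give single-factor training AUCs near 0.88 and
  two-factor AUCs near 0.95, the range typical of published
  cytokine-combination models.
* **True score**: the summed planted S2 log-effects of a patient's hits
  (responders score 2.0). With partial-hit fraction q among
  non-responders the responder-vs-non-responder mean difference is
  2·(1 − q) exactly; it is exactly 2.0 in the no-partial-hit limit.
* **Survival**: Weibull (default shape 1) PFS and OS with log-hazard
  γ·true-score (γ = −0.5: responders' hazard ×e⁻¹), baseline medians 120
  and 300 days, censoring uniform over days 365–730. Clinical benefit is
  therefore correlated with but not identical to R/NR; a 0.5%
  best-response flip probability adds radiology-misclassification noise.
* **Null cohorts** empty the effect map and set γ = 0: labels, cytokines
  and survival become mutually independent (type-I harness).

What passing tests on this harness do **not** show: real plasma panels
have heavier tails, below-quantification censoring, batch effects,
cytokine-specific correlation structure, and effect sizes that are
unknown — the generator demonstrates procedure correctness and
calibration, not clinical performance.

## Problem sizes used in the shipped checks

Calibration checks run 50 simulated cohorts per condition (planted and
null) at the 67 + 24 cohort size; the exact Wilcoxon oracle covers all
two-group splits of up to 10 distinct values; the AUC oracle 1000 random
tied instances up to n = 50; the stepwise oracle exhaustive subsets up to
10 features; hazard-ratio recovery uses 500 patients per arm, reported as
the median over five replicates (the single-draw sampling SD of the HR at
that size is ~0.13, so one replicate conflates estimator correctness with
draw luck).

## Known limitations

* The screen's gate calibration assumes an independent validation cohort;
  with `X_val = X_train` the procedure degenerates to gated forward
  selection and the null calibration no longer applies.
* LDA error rates are resubstitution estimates and optimistic by
  construction; use the CV utility for honest error.
* The DeLong variance degenerates for identical rankings; the comparison
  then reports p = 1.
* No multivariable Cox adjustment is provided; hazard ratios are
  univariate by design.
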