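# cytoratio

Discovery pipeline for longitudinal plasma-cytokine biomarkers of
chemo-immunotherapy response, built around the ratio biomarker
**IP-10(S2/S0) / IL-8(S2/S0)** — the week-10–12-over-baseline change of
the chemokine IP-10 (CXCL10) divided by that of IL-8 (CXCL8).

## Who this is for

Biostatisticians and translational researchers analyzing multiplex plasma
cytokine panels (27-plex, pg/mL) sampled at three timepoints — baseline
(S0), weeks 4–6 (S1), weeks 10–12 (S2) — in cohorts treated with anti-PD-1
immunotherapy plus chemotherapy, with best-overall-response categories
(CR/PR/SD/PD) and PFS/OS follow-up. The package reproduces the full
discovery procedure as reusable, tested components, and ships a synthetic
cohort generator so every stage can be exercised and calibrated without
patient data.

## What it computes

1. **Features.** From 27 cytokines × 3 timepoints it builds 162 log2-scale
   candidates: the three per-timepoint levels plus the three ratios
   S1/S0, S2/S0, S2/S1 (differences of log2 levels), `c@S2/S0` style ids.
2. **Endpoints.** Responder vs non-responder (R = CR/PR/SD, NR = PD) and
   clinical benefit (CB = PFS > 180 days, strict).
3. **Volcano screen.** Per-feature two-sided Wilcoxon rank-sum tests
   (exact enumeration for small samples, tie/continuity-corrected normal
   otherwise) with the gates |log2 FC| > 1.0 and −log10 p > 1.3.
4. **Classical models**, from first principles: logistic regression by
   Newton/IRLS with Wald tests, greedy stepwise-AIC selection,
   pooled-covariance LDA with apparent error, rank-based AUC, and
   seed-controlled stratified 5-fold cross-validated AUC (80/20).
5. **Joint factor screening** — the core algorithm.  Forward selection on
   the training cohort held accountable to an independent validation
   cohort: candidates ranked by training likelihood; the top candidate is
   accepted only if every coefficient has Wald p < α (0.05) **and** the
   evaluation function — the validation-cohort deviance of the
   training-fitted model — has improved by more than k (= 2) per included
   factor.  The audit trace reports training and validation AUC at every
   step.
6. **Ratio collapse.**  A two-factor logistic model with opposite-sign
   coefficients (IP-10 up, IL-8 down) collapses to the single score
   log2 IP-10(S2/S0) − log2 IL-8(S2/S0); the AUC cost of the collapse is
   measured exactly (zero when the coefficient magnitudes match) with a
   DeLong paired test.
7. **Cutoffs and survival.**  Youden-optimal ROC threshold (maximum
   sensitivity + specificity) on the ratio score, reported on the raw
   ratio scale, plus the equivalent model-probability threshold; then
   Kaplan–Meier curves (Greenwood variance), two-group log-rank tests
   (O−E with hypergeometric variance), and univariate Cox hazard ratios
   (Efron ties) for PFS and OS, with histology/drug subgroup re-runs.

## Worked example

```python
import cytoratio as cr

cohort, truth = cr.generate_cohort(cr.SyntheticConfig(seed=1))
fm = cr.build_features(cohort)                     # 91 patients x 162
disc, val = cohort.split()
y_tr = (disc.labels()["rnr"] == "R").astype(int).to_numpy()
y_va = (val.labels()["rnr"] == "R").astype(int).to_numpy()
X_tr, X_va = fm.values.iloc[:67], fm.values.iloc[67:]

result = cr.joint_factor_screen(X_tr, y_tr, X_va, y_va)
print(cr.screening_report(result).to_string(index=False))
```

```
             cytokines  auc_train  auc_val  eval_function           coefficient_p
           IP-10@S2/S0      92.23    89.92          15.21             2.29637e-06
IP-10@S2/S0+IL-8@S2/S0      99.15    98.32          10.26 0.00010853, 0.000368562
```

The screen recovers the two planted change features; the evaluation-
function column is the validation deviance, dropping as each factor buys
out-of-sample fit. Collapsing the model and stratifying survival:

```python
biomarker, fidelity = cr.collapse_to_ratio(result.model, X_tr, y_tr)
from cytoratio.survival import roc_curve, dichotomize, stratified_survival
roc = roc_curve(biomarker.score(X_tr), y_tr)
biomarker.cutoff = roc.youden_optimal
print(biomarker.raw_cutoff, fidelity["delta_auc"])   # 2.53  0.0
high, _ = dichotomize(biomarker.score(X_tr), biomarker.cutoff)
st = stratified_survival(disc.df["os_days"], disc.df["os_event"], high, "os")
print(st.logrank.p_value, st.hr.hazard_ratio)        # 0.0057  0.334
```

Patients above the ratio cutoff 2.53 (higher IP-10 rise relative to IL-8)
show longer overall survival (log-rank p = 0.006; hazard ratio 0.33,
high- vs low-ratio group). The collapse loses no AUC here because the two
fitted coefficients have nearly equal magnitude.

The same analysis runs end to end from the shell:

```bash
cytoratio simulate --seed 1 --out cohort.tsv --truth truth.tsv
cytoratio run -c config.yaml          # features -> volcano -> stepwise ->
                                      # joint screen -> ratio -> survival
cytoratio validate --run-dir out/ --cohort new_cohort.tsv
```

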