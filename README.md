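# sepsisphase

Identify hospitalized patients in the **early-to-peak phase of sepsis** —
the interval from onset of deterioration to the worst septic state — by
combining a single blood draw's multiplexed biomarker panel with electronic
medical record (EMR) vital-sign and laboratory data.

The package is aimed at biostatisticians and clinical-ML researchers who
want a tested, reusable implementation of this analysis style: engineered
features from censored immunoassay panels and irregular clinical time
series, repeated cross-validated model comparison, and per-phase
stratification of predictions. Because cohorts of this kind are rarely
deposited, the package ships a seeded synthetic cohort generator with
analytic ground truth, and every statistical property is validated against
independent oracles on generated data.

## What it computes

* **EMR threshold-excursion score** — each vital/lab series v(t) collapses
  to (1/T)·∫ p(v(t)) dt over a window anchored at the draw, where
  p(v) = (L−v)/L below the normal range [L, U] and (v−U)/U above it
  (step interpolation between charting times; 16 parameters by default).
* **Censored biomarker features** — per-marker censored-MLE log-normal fit
  (ln X ~ N(μ, σ²)); readings outside the detection limits are replaced by
  the truncated-mean conditional expectation, e.g.
  E[X | X < b] = e^{μ+σ²/2}·Φ((ln b−μ−σ²)/σ)/Φ((ln b−μ)/σ),
  then mapped to within-cohort quantile ranks (15 markers: TNF-α, IL-1β,
  G-CSF, IL-6, PCT, sTREM-1, IL-18, MMP-9, TNFR1, TNFR2, IP-10, MCP-1,
  IL-1ra, NGAL, nCD64).
* **Severity scores** — SIRS, qSOFA and SOFA from draw-time snapshots.
* **Repeated stratified 10-fold CV** of five classifier families with the
  Mann-Whitney AUC = P(score⁺ > score⁻) (ties ½), labels 2–5 vs 1, 6–11
  over the 11 adjudication categories; fold-aligned ("paired") across
  models so two models' AUC distributions can be compared by the fraction
  of paired differences above zero and the mean difference.
* **Feature selection** — LASSO support extraction, or
  importance-ranking + greedy prefix search maximizing CV AUC.
* **SOFA regression** — per-fold Spearman ρ for predicting log(SOFA+1)
  from the 23 non-SOFA-criterion features.
* **Stratification** — per-category sensitivity/specificity at cutoff 0.5,
  probability-ranked heatmap table with confusion quadrants, and
  per-category linear-SVM weight profiles.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
from sepsisphase.synthetic import calibrated_config, generate_cohort
from sepsisphase.features import build_feature_matrix
from sepsisphase.modeling import ModelSpec, repeated_cv
from sepsisphase.comparison import paired_auc_comparison

# two-class cohort with biomarker-block Bayes AUC 0.80, EMR-block 0.75
cohort = generate_cohort(calibrated_config(seed=1, n_patients=450))
fm = build_feature_matrix(cohort)          # 450 patients x 31 features

spec = ModelSpec("linear_svm")
cv = {b: repeated_cv(fm.block(b), spec, repeats=50, seed=1)
      for b in ("all", "biomarkers", "emr_scores")}
for b, r in cv.items():
    print(f"{b:12s} mean CV AUC = {r.mean:.3f}")
comp = paired_auc_comparison(cv["all"], cv["emr_scores"])
print(f"combined beats EMR-only in {comp.proportion_above_zero:.0%} "
      f"of {comp.n_pairs} paired folds")
```

Output (seed 1):

```
all          mean CV AUC = 0.807
biomarkers   mean CV AUC = 0.766
emr_scores   mean CV AUC = 0.733
combined beats EMR-only in 87% of 500 paired folds
```

The combined feature set outranks either block alone, and the paired
fold-level comparison quantifies how consistently: most cross-validation
folds scored higher with biomarkers added to the EMR data, mirroring the
study design this pipeline implements.

A full end-to-end run (simulate → featurize → score → train → select →
compare → stratify, with provenance JSON next to every table):

```sh
sepsisphase -v run-all --config src/sepsisphase/data/demo.yaml --out demo_output
```

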