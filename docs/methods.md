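# Methods

`sepsisphase` implements an analysis pipeline for identifying hospitalized
patients in the *early-to-peak phase* of sepsis — the interval from the
onset of deterioration to the worst septic state — from a single blood
draw's multiplexed biomarker panel combined with electronic-medical-record
(EMR) vital-sign and laboratory data. Since the clinical cohort that
motivates the design is not publicly deposited, the pipeline is exercised
end-to-end on a synthetic cohort generator with analytic ground truth; every
statistical claim in the test suite is about *method* behaviour under known
conditions, not about real patients.

## Labels

Each patient carries one of 11 retrospective adjudication categories
describing their sepsis phase at draw time: 1 never septic; 2 approaching
sepsis with deterioration; 3–5 currently in sepsis / severe sepsis / septic
shock; 6–8 recovering with residual inflammation (from sepsis / severe
sepsis / septic shock); 9–11 recovered. Classification treats categories
2–5 as positive and 1, 6–11 as negative, so the model must separate active
deterioration not only from health but also from recovery.

## Feature engineering

**EMR threshold-excursion score.** Each charted parameter (16 by default:
pulse, temperature, respirations, systolic/diastolic BP, MAP, SpO₂, WBC,
lactate, PCO₂, glucose, creatinine, platelets, bilirubin, BUN, hemoglobin)
is collapsed to one number per patient: the time-normalized integral of
percent deviation beyond its clinical normal range \[L, U\],

  score = (1/T) ∫ p(v(t)) dt,  p(v) = (L−v)/L if v<L, (v−U)/U if v>U, else 0,

over a window anchored at the draw time (default 48 h before to 1 h after;
the post-draw extent is studied on the grid 0, 1, 4, 8, 12, 16, 20, 24 h).
Numerical choices: the series is a left-constant step function between
charting times (the last value holds to the window end; nothing is
extrapolated before the first in-window observation, and observations
before the window start do not carry in), window boundaries are closed, the
percent deviation is taken relative to the violated bound, and the
normalizer is the full window duration T rather than the abnormal-time
duration — so "never charted abnormal" and "never charted" both score 0,
with a companion missingness indicator emitted whenever a patient lacks a
parameter entirely. Default normal ranges follow the SIRS limits for the
vital signs and common reference intervals for labs; all are configurable.
The integral over the step function is computed exactly (it is a finite
Riemann sum), and tests verify it against dense-grid numerical integration
to 1e−9.

**Censored biomarker panel.** The 15-marker panel (TNF-α, IL-1β, G-CSF,
IL-6, PCT, sTREM-1, IL-18, MMP-9, TNFR1, TNFR2, IP-10, MCP-1, IL-1ra,
NGAL, nCD64) arrives with readings pinned at the assay's lower/upper limit
of detection (LLOD/ULOD) when out of range. Each marker is fitted with a
log-normal by censored maximum likelihood (observed readings contribute
densities, censored readings the corresponding tail probabilities, on the
log scale; Nelder–Mead on (μ, log σ)); censored readings are then replaced
by the conditional expectation E\[X | X < LLOD\] or E\[X | X > ULOD\] of the
fitted distribution, using the closed-form truncated log-normal mean
evaluated in log space for tail stability. The log-normal family is a
modelling choice — cytokine concentrations are classically right-skewed and
positive — and the processing order is impute-then-quantile; both facts are
surfaced in the feature file's provenance JSON. Markers with fewer than 3
observed values, or degenerate spread, fall back to imputation at the limit
itself. Finally each marker is mapped to within-cohort quantile ranks
rank/(n+1) (ties averaged) for outlier robustness. Distribution fits use
the full cohort before CV splitting, mirroring the original preprocessing
order; leakage-free refitting inside training folds is available by passing
per-fold fits to `biomarker_features`. nCD64 is an expression index rather
than a plasma concentration but is processed identically (a documented
simplification). Batch identifiers are retained on every measurement so
batch covariates can be added, but assay-side calibration is out of scope.

## Severity scores

SIRS (4 criteria), qSOFA (3 criteria) and SOFA (six 0–4 organ subscores)
are computed from a draw-time snapshot using the consensus criterion
tables, with boundary conventions unit-tested (e.g. SBP ≤ 100 counts for
qSOFA). Missing components score 0 — the standard clinical convention —
and SOFA reports the fraction of organ systems with any data. The SOFA
respiration subscore uses the PaO₂/FiO₂ ratio alone (ventilatory support is
not a snapshot field), and cardiovascular support is encoded as a 0–3
vasopressor tier. Draw-time values feed the scores; worst-in-24-h
aggregation is deliberately not implemented (callers provide the snapshot).

## Models and evaluation

Five classifier families (logistic regression, linear SVM, random forest,
AdaBoost with depth-1 trees and 100 rounds, Gaussian naive Bayes) and four
regressor families are wrapped behind one `ModelSpec` surface (scikit-learn
underneath). The SVM kernel is linear so its weight vector doubles as a
feature-importance profile; probabilities from margin classifiers come from
Platt-style sigmoid calibration fitted on training data.

Performance is estimated by repeated stratified 10-fold cross-validation:
per repetition a fresh seeded partition; per fold, features are z-scored on
the training portion, the model fitted, and the held-out fold scored with
the Mann-Whitney AUC (fraction of positive/negative pairs correctly
ordered, ties ½). Fold partitions are derived from the seed alone — never
from the model — and hashed into a fingerprint, so two models run under the
same seed are fold-aligned. The default is 1000 repetitions (10,000 fold
AUCs); tests and the acceptance script use 50 to keep runs desk-scale. The
reported value is the mean of per-fold AUCs (not pooled predictions).
Degenerate folds are skipped and counted, never silently averaged.

**Paired comparison.** Two fold-aligned models are compared by the
distribution of element-wise AUC differences: the proportion strictly above
zero (ties reported separately, making self-comparison well-defined), the
mean difference, and 2.5/50/97.5% quantiles. No formal hypothesis test is
attached; the statistic is descriptive.

**SOFA regression.** A separate task predicts log(SOFA + 1) (the +1 avoids
−∞ at SOFA 0) from the 23 features remaining after excluding the 8 columns
that enter SOFA's criteria or proxy its organ systems (systolic/diastolic
BP, MAP, SpO₂, platelets, bilirubin, creatinine, BUN); performance is the
per-fold Spearman correlation between held-out predictions and the target,
reported as (mean, sd).

**Feature selection.** For logistic regression and naive Bayes: L1
penalized logistic regression with the penalty chosen at minimum inner
5-fold CV deviance over a 15-point grid; nonzero-coefficient features are
kept. For SVM/RF/AdaBoost: features are ranked once (|SVM weight| on
standardized features, or out-of-fold permutation mean-decrease-in-accuracy
for the ensembles — the ranking is fixed, not recomputed after each
addition), then every ranking prefix is scored by CV AUC and the global
argmax kept, ties broken toward the smaller prefix; the full AUC trace is
exported so a first-local-maximum reading can be audited. By default
selection runs on the full dataset and is then evaluated by repeated CV —
this mirrors the select-then-evaluate order the design targets and is
optimistically biased; nested per-fold selection can be composed from the
same primitives.

**Stratification.** Predictions are decomposed over eight category groups
({1, 9–11} pooled, then 2…8 singly): sensitivity for positive groups and
specificity for negative groups at probability cutoff 0.5 (a probability
exactly at the cutoff counts as predicted positive; empty groups report
undefined, not 0), plus mean/sd of predicted probability and n. A heatmap
table ranks patients by descending probability (stable ties) with
confusion-matrix quadrants, and per-category feature profiles are the
unit-norm weight vectors of one-vs-rest linear SVMs per group — a
construction choice recorded in output metadata and swappable.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes.
Each patient draws a category from a configurable 11-way mix, then a latent
severity from a category-specific normal (early-to-peak categories 2–5
ordered increasing, recovery 6–8 intermediate, others lowest; sd 1).
Biomarker log-concentrations are baseline + per-category shift ×
`biomarker_signal` + severity coupling (organ-dysfunction markers: PCT,
NGAL, sTREM-1, TNFR1/2, MMP-9) + a shared N(0, 0.15²) log-scale batch
effect per 40-sample assay batch + unit log-noise, censored at the
configured LLOD/ULOD (defaults give a few percent left-censoring). Vitals
are charted on a jittered regular grid spanning 48 h before to 24 h after
the draw; values are baseline + gain × `emr_signal` × severity × sd +
charting noise, with the gain's sign setting the abnormal direction, and an
optional onset-after-draw mode that confines the severity term to post-draw
times. The draw-time snapshot (and hence SOFA) is coupled to the same
severity. All randomness flows from one seed through named `SeedSequence`
child streams, so cohorts are byte-identical across reruns.

`calibrated_config` builds two-class study conditions with prescribed
block-level Bayes AUCs: one informative marker (IL-6) carries the full
biomarker separation √2·Φ⁻¹(AUC_bio), and the severity shift carries
√2·Φ⁻¹(AUC_emr); vital baselines are pinned at their violated threshold so
the excursion score is a strictly monotone transform of severity and the
rank-based AUC survives the nonlinearity. Defaults: AUC 0.80 for the
biomarker block vs 0.75 for the EMR block, n = 450, 30% positive.

What the generator does **not** model: physiological dynamics or
autocorrelated vitals (observations are independent around the
severity-shifted mean), missingness beyond detection limits, assay
chemistry (batch effects are a multiplicative stand-in for batch-wise
calibration), treatment effects, or any quantitative match to a real
cohort's Table-1-style composition. Passing tests therefore demonstrate
that the estimators recover known structure under clean generative
assumptions — not that the pipeline attains any particular AUC on real
patients.

## Test design and problem sizes

Oracle tests pin each primitive to an independent reference: exhaustive
pair counting for the AUC, 1-second dense-grid integration for the
excursion score, quadrature and 10⁶-draw Monte Carlo for the truncated
log-normal mean, and the binormal closed form Φ(d/√2) for CV recovery.
Two finite-sample facts shape the statistical checks. First, one fixed
dataset's empirical AUC has sampling sd ≈ 0.017 at n = 450, so closed-form
recovery checks average three independent cohorts. Second, repeated CV on
a single fixed null dataset is *not* centred exactly at chance: held-out
folds share the dataset's idiosyncratic spurious direction, inflating the
null mean by roughly a √(p/n)-scale term, so null-band checks use large
n relative to the feature count (n = 2000 for one feature; averages over
independent datasets for the 24-feature regression null). Simulation-heavy
checks (selection recovery, feature-set ordering, the window curve) run at
n = 300–450 with 15–50 CV repeats and 20–50 seeded replicate runs — sizes
chosen so each property's pass probability under its own design is well
above the asserted fraction.

## Known limitations

* The excursion-score integrand and normalizer are one reasonable reading
  of a time-normalized percent-deviation Riemann sum; alternatives
  (normalizing by abnormal time, back-extrapolating the first observation)
  would change absolute scores, though not their zero point.
* Full-cohort imputation and full-dataset selection are optimistically
  biased relative to fully nested variants; both orders are available.
* The generator's independence assumptions (noise across markers and
  across charting times) make recovery easier than real EMR data would be.
* Category-specific weight profiles from one-vs-rest linear SVMs are one of
  several defensible constructions for per-phase feature importance.
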