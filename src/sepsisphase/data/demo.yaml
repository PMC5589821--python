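# Demo run: small synthetic cohort, reduced repeats, all stages.
out: demo_output
seed: 7
simulate:
  n_patients: 220
hours_before: 48.0
hours_after: 1.0
models: [logistic_regression, linear_svm, naive_bayes]
feature_sets: [all, emr_scores, biomarkers]
repeats: 10
selection: true
selection_model: linear_svm
cutoff: 0.5
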