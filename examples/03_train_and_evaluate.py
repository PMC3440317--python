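"""Cross-validate the predictor on a planted-signal benchmark.

Runs five-fold cross-validation of the combined (similarity x propensity)
encoding on a balanced synthetic dataset, reporting sensitivity, precision
and F-measure at the max-F operating point plus the ROC AUC, with 95%
confidence half-widths over folds.
"""

import tripitope as tp

dataset, background, spec = tp.benchmark_dataset(n_per_class=400, L=20, seed=3)
cv = tp.cross_validate(dataset, background, mode="combined")
s = cv.summary()
print(f"five-fold CV on {2 * len(dataset.positives)} peptides (L=20):")
print(f"  Sn  = {100 * s['sn']:.1f}% +/- {100 * s['sn_ci']:.1f}%")
print(f"  P   = {100 * s['p']:.1f}% +/- {100 * s['p_ci']:.1f}%")
print(f"  F   = {s['f']:.3f} +/- {s['f_ci']:.3f}")
print(f"  AUC = {s['auc']:.3f}")
print("AUC well above 0.5 shows the planted tri-peptide enrichment is "
      "recovered from held-out folds; propensity tables are re-estimated "
      "inside each fold, so no test peptide leaks into training.")
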