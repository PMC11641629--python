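"""Train the logistic meta-model and flag unreliable predictions.

The meta-model maps the uncertainty features to the probability that a
prediction falls in the worst 15% by absolute error; rows with
probability >= 0.15 are flagged.
"""

import molue
from molue import ensemble as ens
from molue import meta

config = molue.SimulationConfig(n_molecules=400, m_models=4, seed=3)
entries, _ = molue.make_prediction_table(config)
ue = molue.build_features_crossval(entries, n_folds=5, seed=3, k=10)

abs_err = ue["abs_error"].to_numpy()
d_t = ens.compute_threshold(abs_err, 0.85)
labels = ens.label_predictions(abs_err, d_t)

X = meta.assemble_features(ue, "logistic")
clf = meta.fit_logistic(X, labels)
print("logistic coefficients (value +/- standard error):")
print(f"  intercept        {clf.intercept:+8.4f} ({clf.intercept_se:.4f})")
for name, c, se in zip(clf.feature_names, clf.coef, clf.stderr):
    print(f"  {name:<16} {c:+8.4f} ({se:.4f})")

probs = clf.predict_proba(X)
report = meta.evaluate(probs, labels, p_threshold=0.15)
print(f"\nROC-AUC {report.roc_auc:.3f}  F1 {report.f1:.3f}  "
      f"precision {report.precision:.3f}  recall {report.recall:.3f}")
print(f"confusion: TP={report.tp} TN={report.tn} "
      f"FP={report.fp} FN={report.fn}")

flags = clf.flag(X)
mae_ok = abs_err[flags == 0].mean()
mae_bad = abs_err[flags == 1].mean()
print(f"\nflagged {flags.sum()} of {len(flags)} predictions")
print(f"MAE of predictions kept:    {mae_ok:7.1f}")
print(f"MAE of predictions flagged: {mae_bad:7.1f}")

# The flagged group should carry a severalfold larger mean absolute
# error than the kept group: that gap is what makes the flag useful
# for screening candidate identifications.
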