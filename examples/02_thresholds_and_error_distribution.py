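"""Error thresholds D_t and the shape of the error distribution.

A prediction is "unsatisfactory" when its absolute error exceeds D_t,
the empirical quantile that leaves a chosen fraction (default 85%) of
the data set satisfactory.  Absolute errors of property-prediction
ensembles are exponential-tailed rather than normal, which this
example demonstrates on simulated errors.
"""

import numpy as np

import molue

config = molue.SimulationConfig(n_molecules=400, m_models=4, seed=2)
entries, _ = molue.make_prediction_table(config, couple_chemistry=False)
abs_err = np.array([
    abs(molue.ensemble_prediction(e.model_preds) - e.y_true) for e in entries
])

thresholds = molue.compute_thresholds(abs_err)
for f, d_t in sorted(thresholds.thresholds.items()):
    flagged = molue.label_predictions(abs_err, d_t).sum()
    print(f"f = {f:.2f}  ->  D_t = {d_t:7.2f}  ({flagged} unsatisfactory)")

exp_fit = molue.fit_error_distribution(abs_err, "exponential")
norm_fit = molue.fit_error_distribution(abs_err, "normal")
print(f"exponential rate lambda = {exp_fit.rate:.4f} (= 1 / mean |error|)")
print(f"log-likelihood: exponential {exp_fit.log_likelihood:.1f} "
      f"vs normal {norm_fit.log_likelihood:.1f}")
print(f"P(|error| > D_t(0.85)) under the exponential fit: "
      f"{molue.tail_probability(exp_fit, thresholds[0.85]):.3f}")

# D_t grows steeply with f because of the exponential tail; the
# exponential log-likelihood exceeding the normal one means large
# errors are far more common than a Gaussian model would predict.
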