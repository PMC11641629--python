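"""Simulate a prediction study and compute uncertainty features.

Builds a small synthetic data set (molecule library + 4-model ensemble
whose error magnitude follows a latent difficulty tied to chemical
rarity), then computes the out-of-fold uncertainty-estimation features
for every molecule.
"""

import molue

config = molue.SimulationConfig(n_molecules=200, m_models=4, seed=0)
entries, difficulty = molue.make_prediction_table(config)
print(f"simulated {len(entries)} molecules, ensemble of {config.m_models}")
print("first molecule:", entries[0].smiles,
      f"y_true={entries[0].y_true:.1f}",
      "preds=", [round(p, 1) for p in entries[0].model_preds])

ue = molue.build_features_crossval(entries, n_folds=5, seed=1, k=10)
cols = ["smiles", "abs_error", "m_s1", "s_max_t", "s_max_e", "d_cl", "mae_cl"]
print(ue[cols].head(5).round(3).to_string(index=False))

# m_s1: ensemble-member disagreement (property units); s_max_t /
# s_max_e: nearest-training-set Tanimoto similarity / PC-space
# distance; d_cl: centroid distance over the cluster average; mae_cl:
# mean absolute error of the molecule's cluster.  Large spread, low
# similarity, and a far/inaccurate cluster all signal an unreliable
# prediction.
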