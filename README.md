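# molue — uncertainty estimation for molecular-property predictions

Machine-learning models that predict mass-spectrometry-related
properties of small molecules — gas-chromatographic retention indices
(RI), HPLC retention times (RT, seconds), ion-mobility collision
cross-sections (CCS, Å²) — usually return a single number with no
indication of how much to trust it. In non-targeted metabolomics and
environmental analysis those predictions are used to discard wrong
candidate identifications, so an unreliable prediction that goes
unflagged can silently corrupt an identification. `molue` is a
model-agnostic toolkit for exactly that problem: given a table of
per-molecule ensemble predictions and the training-set structures, it
estimates, for every prediction, the probability that it falls into
the worst error fraction (15% by default), and flags it.

## The method

A prediction is called **unsatisfactory** when its absolute error
exceeds a threshold *D*<sub>t</sub>, the empirical quantile chosen so
that a target fraction *f* (default 85%) of the data set is
satisfactory. Three independent signals are computed per molecule:

* **Ensemble spread** — disagreement of the *m* ensemble members
  around the ensemble prediction:
  *M*<sub>s1</sub> = mean |p<sub>i</sub> − ŷ|,
  *M*<sub>s2</sub> = RMS deviation, *M*<sub>m</sub> = max − min.
* **Molecular similarity to the training set** — the best similarity
  between the query and any training molecule:
  *S*<sub>max,t</sub> (Tanimoto on binarized circular count
  fingerprints, radius 3, 8192 positions), *S*<sub>max,c</sub>
  (cosine on the raw counts), *S*<sub>max,e</sub> (minimum Euclidean
  distance between 20-component PCA projections of min-max-scaled 2D
  descriptors), and optionally *S*<sub>max,mcs</sub>
  (maximum-common-substructure similarity
  *S* = *X*/(*A* + *B* − *X*), atoms + bonds).
* **Chemical-space clustering** — *k*-means (k = 20) in the same PCA
  space; features are the cluster's error statistics
  MAE<sub>cl</sub> / MdAE<sub>cl</sub> and the normalized centroid
  distance *D*<sub>cl</sub> = *D*/*D*<sub>mean</sub>.

A logistic regression on {MAE<sub>cl</sub>, *D*<sub>cl</sub>,
*S*<sub>max,t</sub>, *S*<sub>max,e</sub>, *M*<sub>s1</sub>, ŷ/1000}
— or a gradient-boosting classifier (100 depth-3 trees, learning rate
0.1) on the full feature set — outputs the probability that the
prediction is unsatisfactory; rows with probability ≥ *p* = 0.15 are
flagged. Absolute errors of such ensembles are exponential-tailed
rather than Gaussian, which is why the package predicts
threshold-exceedance probabilities instead of standard deviations; the
`ensemble` module also provides the corresponding distribution
diagnostics (exponential/normal/Cauchy maximum-likelihood fits).

All features for a query are computed strictly out-of-fold: the
scaler, PCA, clusters, cluster error statistics, and similarity
reference are fit on training folds that never contain the query
molecule (folds are molecule-level).

Because the real benchmark sets are large and partly proprietary, the
`synth` module generates complete synthetic studies: a combinatorial
library of valid small molecules, a smooth retention-like property,
and ensembles whose Laplace-tailed errors follow a latent difficulty
that can be coupled to chemical rarity.

## Worked example

`examples/03_flag_unreliable_predictions.py` simulates a 400-molecule
study, computes out-of-fold features, and fits the logistic
meta-model:

```
logistic coefficients (value +/- standard error):
  intercept         -4.7144 (1.3180)
  mae_cl            +0.0256 (0.0109)
  d_cl              +0.5780 (0.3269)
  s_max_t           +1.9652 (1.1828)
  s_max_e           +0.2414 (0.3429)
  m_s1              +0.0096 (0.0027)
  y_ens_over_1000   -1.0079 (0.7935)

ROC-AUC 0.773  F1 0.424  precision 0.304  recall 0.700
confusion: TP=42 TN=244 FP=96 FN=18

flagged 138 of 400 predictions
MAE of predictions kept:       32.0
MAE of predictions flagged:    72.0
```

The ensemble-spread coefficient (`m_s1`) is strongly significant —
spread is the single best predictor of unreliability — and the flagged
group's mean absolute error is more than twice that of the kept group,
which is what makes the flag useful for screening candidates. The
other examples cover feature computation (`01`), error thresholds and
the exponential error tail (`02`), and the similarity measures and
cluster error profiles (`04`).

## Command line

The same stages are available as a CLI for scripted runs:

```bash
molue simulate --n 400 --seed 0 --out table.csv
molue featurize --table table.csv --out features.csv
molue thresholds --features features.csv --out thresholds.json
molue train-meta --features features.csv --kind logistic --model-out model.json
molue flag --features features.csv --model model.json --out flags.csv
molue evaluate --features features.csv --model model.json --out report.json
```

A YAML config (`--config`) can hold shared defaults; explicit flags
win, and each command writes its resolved settings next to its output.

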