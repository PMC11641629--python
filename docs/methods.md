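# Methods

## Problem formulation

Given a base model (or ensemble) that predicts a molecular property,
the goal is not to improve the prediction but to estimate, per
molecule, the probability that the prediction is *unsatisfactory*:
that its absolute error |Δ| exceeds a threshold *D*<sub>t</sub>.
*D*<sub>t</sub> is the empirical *f*-quantile of the absolute errors
of the data set (linear-interpolation quantile; a strict `>` defines
the unsatisfactory label, so the boundary value is satisfactory).
Default *f* = 0.85, i.e. 15% of predictions are unsatisfactory by
construction. The exceedance formulation is preferred over predicting
a standard deviation because the empirical error distributions of
property-prediction ensembles are exponential-tailed: a Gaussian
read-out would badly underestimate the frequency of large errors. The
`ensemble` module provides maximum-likelihood fits to make that
diagnosis on any data set (exponential on |Δ| with closed-form
λ = 1/mean, normal and Cauchy on signed Δ, Cauchy via numerical MLE)
together with `tail_probability` for converting a fit into exceedance
probabilities.

## Features

For each molecule the package computes the feature vector

| group | features | notes |
|---|---|---|
| cluster | *N*<sub>cl</sub>, MAE<sub>cl</sub>, MdAE<sub>cl</sub>, *D*<sub>cl</sub> | k-means in PC space, k = 20 |
| similarity | *S*<sub>max,t</sub>, *S*<sub>max,c</sub>, *S*<sub>max,e</sub>, (*S*<sub>max,mcs</sub>) | best value over the training set |
| spread | *M*<sub>s1</sub>, *M*<sub>s2</sub>, *M*<sub>m</sub> | about the ensemble prediction |
| scale | ŷ (ensemble prediction) | larger values ⇒ larger absolute errors |

**Chemical-space representation.** The full RDKit 2D descriptor set
(210 descriptors, including the `fr_*` functional-group counters) is
computed per molecule; failed or non-finite descriptor values are
imputed to 0 with a logged warning. Descriptors are min-max scaled to
[0, 1] on the fitting set; constant columns map to 0 and out-of-range
query values are deliberately *not* clipped so that distances stay
meaningful for chemical outliers. A PCA retaining
c = min(20, d, n − 1) components follows; component signs are fixed
(largest-magnitude loading positive) for bitwise reproducibility. The
method is descriptor-set-agnostic — any sufficiently rich 2D set
yields the same qualitative behaviour — so internal consistency, not a
specific descriptor list, is what the tests pin down.

**Similarity measures.** Count fingerprints are hashed circular
environments (radius 3, folded to 8192 positions, counts accumulate on
collisions). Tanimoto similarity is computed on the binarized on-sets
(counts provably do not change it); cosine similarity uses the raw
counts, where they do matter. The Euclidean measure is the L2
distance between PC vectors, reported as a minimum over the training
set where the others report maxima. MCS similarity is
*S* = *X*/(*A* + *B* − *X*) with *X*, *A*, *B* counting heavy atoms
plus bonds; matching requires equal elements, aromatic atoms only
match aromatic atoms, equal bond order, and ring bonds only match ring
bonds; the search is the toolkit's connected-MCS with a configurable
timeout (default 10 s per pair) returning a flagged best-so-far result
on expiry. MCS is one to two orders of magnitude slower than the
other measures and is therefore off by default in the pipeline.
`nearest_similarity` has plain linear-scan semantics; the test suite
verifies it against a brute-force scan and verifies the MCS against an
exhaustive connected-common-subgraph enumeration on molecules with ≤ 8
heavy atoms.

**Clustering.** Lloyd's k-means (k-means++ seeding, best of 10
restarts, tolerance 1e-6, Euclidean metric) with a recorded seed —
clustering is stochastic and the assignment is not identifiable across
reruns, only its statistics are. Per-cluster MAE/MdAE (and optionally
mean percentage error) are computed from training-fold molecules only;
clusters that receive no training member fall back to the global
MAE/MdAE with a warning. *D*<sub>cl</sub> divides a query's centroid
distance by the cluster's mean member distance; ties in centroid
assignment break toward the lowest cluster index. The
distance-quartile profile (per-cluster MAE by centroid-distance
quartile) is a diagnostic of the "periphery molecules are predicted
worse" effect; clusters with fewer than 4 members are skipped.

## Meta-models

The linear model is an unregularized maximum-likelihood logistic
regression on six features (MAE<sub>cl</sub>, *D*<sub>cl</sub>,
*S*<sub>max,t</sub>, *S*<sub>max,e</sub>, *M*<sub>s1</sub>, ŷ/1000),
fit with an intercept (reported separately) and with standard errors
from the inverse observed information. Features are not standardized,
so coefficients stay on interpretable raw scales; the ŷ/1000 scaling
keeps that coefficient O(1). Perfect separation and single-class
inputs raise errors rather than returning unstable fits. The
non-linear alternative is gradient boosting with the library defaults
(100 trees, depth 3, learning rate 0.1) on the full feature set (all
real-valued features, one-hot cluster number, raw ŷ), with gain-based
feature importances. The decision threshold is *p* = 0.15 on the
predicted probability (≥ flags), approximately the F1-optimal point
for a 15% positive rate.

**Out-of-fold protocol.** Folds are molecule-level: all records of a
canonical SMILES share a fold, so a molecule is never in the training
side of its own prediction. Within each split, *everything* —
scaler, PCA, k-means, cluster error statistics, similarity reference —
is fit on the training folds only and applied to the held-out fold.
The cluster error statistics use the training molecules' own
out-of-fold ensemble errors, so no query's error leaks into its
features. This is stricter than fitting the chemical-space
infrastructure on the full data set; a `fit_scope`-style whole-set fit
would change feature values only marginally but would blur the
leakage guarantee, so the training-folds-only variant is the one
implemented.

## Data preparation

SMILES are canonicalized with stereochemistry removed (identical
structures ⇒ identical strings; the operation is idempotent).
Molecules are rejected when they have ≥ 10 SSSR rings, a SMILES longer
than 250 characters (checked on the string as written, before
canonicalization), or elements outside {B, C, N, O, F, Si, P, S, Cl,
Br, I} (+ H). Charged or radical species that parse and pass the
element rule are kept. Duplicate structures keep one record chosen
uniformly at random under a recorded seed.

## Synthetic studies

The generator stands in for the real RI/RT/CCS benchmarks, which are
large and partly proprietary. It emulates the statistical structure
the method relies on, with these defaults as the study conditions:

* **Library**: a deterministic combinatorial enumeration (~680
  distinct structures) of linear/branched alkanes, alcohols, amines,
  ethers, halides, ketones, esters, nitriles, and mono-/di-substituted
  benzenes, pyridines, thiophenes, and naphthalenes; all canonical and
  filter-passing.
* **True property**: y = 200 + 80·(heavy atoms) + 40·(heteroatoms) +
  60·(rings) + N(0, 15) — a smooth, positive, retention-like scale
  where a typical molecule sits near 800–1200, comparable to a
  retention-index range.
* **Errors**: per-molecule latent difficulty u ~ U(0, 1); scale
  s = s₀·exp(γ·u) with s₀ = 30 (property units) and γ = 2, giving a
  ~7× spread between the easiest and hardest molecules; a shared bias
  b ~ Laplace(0, κ·s) with κ = 0.3 that ensemble averaging cannot
  remove, plus independent per-model Laplace noise of scale
  (1 − κ)·s. Laplace tails make |Δ| exponential, matching the shape
  observed for real ensembles; κ reflects that member errors of
  same-architecture ensembles are partially correlated.
* **Chemistry coupling**: optionally, u follows the rank of the
  molecule's distance to its 5th nearest neighbor in descriptor PC
  space (70% rarity, 30% chance, re-ranked to a uniform margin), so
  rare chemistry is hard chemistry. This is what gives the
  similarity and cluster features real signal; without it only the
  spread features are informative.

What the generator does **not** emulate: real descriptor–property
relationships (the toy 1-NN base regressor is a stand-in, not a model
of chemistry), multimodal data-set structure, assay noise in y, or the
quantitative value ranges of RI/RT/CCS. Passing tests therefore show
that the machinery is correct and that the qualitative predictor
ordering (spread > similarity > cluster features; combined model ≥
best single) emerges whenever the assumed structure is present — not
that any particular ROC-AUC will be attained on a given real data set.

## Numerical choices and degenerate inputs

* Quantile convention: linear interpolation (type 7); unsatisfactory
  means strictly greater than *D*<sub>t</sub>.
* Tanimoto of two empty fingerprints is 0; cosine against a zero
  vector is 0 with a warning.
* Constant descriptor columns scale to 0 and are flagged.
* A degenerate cluster (D_mean = 0) yields *D*<sub>cl</sub> = 0 at the
  centroid and ∞ elsewhere.
* Ensemble weights must sum to 1; equal weights are the default (the
  unequal-coefficient variant used for one published RI ensemble is
  supported through the same argument).
* Seeds: every stochastic step (deduplication, fold assignment,
  k-means, bootstrap, simulation) takes an explicit seed and is
  bit-reproducible given it.

## Problem sizes

Test and acceptance runs use deliberately small studies — a few
hundred molecules, 3–5 folds, k ≤ 20, 20 000-row logistic recovery
replicates — chosen so the full suite exercises every stage end-to-end
in minutes while leaving the statistical assertions comfortably
powered. The library scales linearly in molecules for everything
except MCS similarity (quadratic in practice and gated behind a flag).

## Known limitations

* The MCS timeout makes *S*<sub>max,mcs</sub> a lower bound on slow
  pairs (flagged, not silently wrong).
* k-means statistics are only as stable as the clustering; the seed is
  recorded, and cluster numbers have no meaning across reruns.
* The logistic model is fit without regularization; with tiny data
  sets or quasi-separable features it will (correctly) refuse to fit.
* Conformal prediction, dropout- and Bayesian-NN-based uncertainty are
  out of scope by design; the package estimates unreliability flags,
  not calibrated predictive intervals.
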