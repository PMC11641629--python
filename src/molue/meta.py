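"""Meta-classifiers that flag unreliable predictions, and the
out-of-fold pipeline that feeds them.

The uncertainty-estimation (UE) feature vector of a molecule combines
three independent signals: how far the molecule sits in chemical space
from the training set (nearest-neighbor similarities), how error-prone
its chemical-space neighborhood is (cluster error statistics and the
normalized centroid distance), and how much the ensemble members
disagree (spread features).  A logistic regression — or a
gradient-boosting classifier with the standard defaults — maps the
features to the probability that the prediction falls into the worst
error fraction, and rows with probability at or above the decision
threshold (0.15 by default) are flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from . import clustering as cl
from . import ensemble as ens
from . import features as ft
from . import similarity as sim
from .io import MoleculeEntry, assign_folds, iter_fold_splits

log = logging.getLogger(__name__)

#: Real-valued UE features in canonical column order.
UE_BASE_FEATURES = (
    "mae_cl", "mdae_cl", "d_cl",
    "s_max_t", "s_max_c", "s_max_e", "s_max_mcs",
    "m_s1", "m_s2", "m_m",
)

#: The six-feature set of the linear meta-model (ensemble prediction
#: enters divided by 1000).
LOGISTIC_FEATURES = (
    "mae_cl", "d_cl", "s_max_t", "s_max_e", "m_s1", "y_ens_over_1000",
)

#: Direction each feature carries: +1 when larger values indicate a
#: possibly larger error, -1 when larger values indicate a smaller one.
FEATURE_ORIENTATION = {
    "mae_cl": 1, "mdae_cl": 1, "d_cl": 1,
    "s_max_t": -1, "s_max_c": -1, "s_max_mcs": -1, "s_max_e": 1,
    "m_s1": 1, "m_s2": 1, "m_m": 1,
}

DEFAULT_P_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class FeatureState:
    """Everything fit on the training folds that queries are scored against."""

    scaler: ft.ScalerParams
    pca: ft.PCAProjection
    clusters: cl.ClusterModel
    reference: sim.SimilarityReference


def fit_feature_state(
    train_smiles: Sequence[str],
    train_abs_errors: Sequence[float],
    k: int = cl.DEFAULT_K,
    seed: int = 0,
    descriptor_cache: dict[str, np.ndarray] | None = None,
    signed_errors: Sequence[float] | None = None,
    y_true: Sequence[float] | None = None,
) -> FeatureState:
    """Fit scaler, PCA, clusters, and the similarity reference.

    ``train_abs_errors`` must be out-of-fold errors of the base model
    on the training molecules, so that the attached per-cluster error
    statistics are unbiased.
    """
    desc = _descriptor_rows(train_smiles, descriptor_cache)
    scaler = ft.fit_scaler(desc)
    scaled = ft.apply_scaler(desc, scaler)
    pca = ft.fit_pca(scaled)
    pcs = ft.project(scaled, pca)
    model = cl.fit_kmeans(pcs, k=min(k, len(train_smiles)), seed=seed)
    cids, dists, _ = cl.assign_clusters(pcs, model)
    cl.cluster_error_stats(model, cids, train_abs_errors,
                           signed_errors=signed_errors, y_true=y_true)
    ref = sim.build_reference(train_smiles, pcs)
    return FeatureState(scaler, pca, model, ref)


def _descriptor_rows(
    smiles: Sequence[str], cache: dict[str, np.ndarray] | None
) -> np.ndarray:
    if cache is None:
        return ft.compute_descriptors(smiles).values
    missing = [s for s in smiles if s not in cache]
    if missing:
        rows = ft.compute_descriptors(missing).values
        cache.update(dict(zip(missing, rows)))
    return np.vstack([cache[s] for s in smiles])


def compute_ue_features(
    entries: Sequence[MoleculeEntry],
    state: FeatureState,
    include_mcs: bool = False,
    weights: Sequence[float] | None = None,
    descriptor_cache: dict[str, np.ndarray] | None = None,
    mcs_timeout_s: float = sim.MCS_TIMEOUT_S,
) -> pd.DataFrame:
    """UE feature table for query molecules against a fitted state.

    One row per entry with the cluster, similarity, and spread features
    plus the ensemble prediction and (when the experimental value is
    known) the absolute error.  The MCS similarity is optional: it is
    one to two orders of magnitude slower than the other measures.
    """
    smiles = [e.smiles for e in entries]
    desc = _descriptor_rows(smiles, descriptor_cache)
    scaled = ft.apply_scaler(desc, state.scaler)
    pcs = ft.project(scaled, state.pca)
    cids, dists, ratios = cl.assign_clusters(pcs, state.clusters)
    s_max_e = cdist(pcs, state.reference.pc_vectors).min(axis=1)

    rows = []
    for i, e in enumerate(entries):
        y_ens = ens.ensemble_prediction(e.model_preds, weights)
        m_s1, m_s2, m_m = ens.spread_features(e.model_preds, y_ens)
        fp = ft.compute_count_fingerprint(e.smiles)
        query = sim.QueryFeatures(e.smiles, fp, pcs[i])
        row = {
            "smiles": e.smiles,
            "y_true": e.y_true,
            "y_ens": y_ens,
            "abs_error": abs(y_ens - e.y_true),
            "fold": e.fold_id,
            "n_cl": int(cids[i]),
            "mae_cl": float(state.clusters.mae[cids[i]]),
            "mdae_cl": float(state.clusters.mdae[cids[i]]),
            "d_cl": float(ratios[i]),
            "s_max_t": sim.nearest_similarity(query, state.reference, "tanimoto"),
            "s_max_c": sim.nearest_similarity(query, state.reference, "cosine"),
            "s_max_e": float(s_max_e[i]),
            "m_s1": m_s1,
            "m_s2": m_s2,
            "m_m": m_m,
        }
        if include_mcs:
            row["s_max_mcs"] = sim.nearest_similarity(
                query, state.reference, "mcs", mcs_timeout_s=mcs_timeout_s
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_features(
    ue: pd.DataFrame, mode: str = "logistic", k: int = cl.DEFAULT_K
) -> pd.DataFrame:
    """Build the model input table from UE feature rows.

    ``logistic`` mode yields the six-feature linear set (cluster MAE,
    D_cl, Tanimoto and Euclidean nearest-neighbor features, M_s1, and
    the ensemble prediction divided by 1000).  ``full`` mode yields all
    real-valued features plus a one-hot encoding of the cluster number
    and the raw ensemble prediction.
    """
    if mode == "logistic":
        cols = {}
        for name in LOGISTIC_FEATURES:
            if name == "y_ens_over_1000":
                if "y_ens" not in ue.columns:
                    raise ValueError("missing feature: y_ens")
                cols[name] = ue["y_ens"] / 1000.0
            else:
                if name not in ue.columns:
                    raise ValueError(f"missing feature: {name}")
                cols[name] = ue[name]
        return pd.DataFrame(cols)
    if mode == "full":
        cols = {}
        for name in UE_BASE_FEATURES:
            if name == "s_max_mcs" and name not in ue.columns:
                continue  # optional measure, included only if computed
            if name not in ue.columns:
                raise ValueError(f"missing feature: {name}")
            cols[name] = ue[name]
        for c in range(k):
            cols[f"n_cl_{c}"] = (ue["n_cl"] == c).astype(float)
        cols["y_ens"] = ue["y_ens"]
        return pd.DataFrame(cols)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# meta-models


@dataclass
class MetaClassifier:
    """Fitted meta-model with its decision probability threshold.

    For the logistic kind, ``coef``/``stderr`` hold the maximum-
    likelihood coefficients and their standard errors (from the inverse
    observed information), with the intercept kept separate.
    """

    kind: str
    feature_names: tuple[str, ...]
    p_threshold: float = DEFAULT_P_THRESHOLD
    intercept: float | None = None
    intercept_se: float | None = None
    coef: np.ndarray | None = None
    stderr: np.ndarray | None = None
    booster: object | None = None  # xgb.XGBClassifier or raw xgb.Booster
    gain_importance: dict[str, float] | None = None

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Probability that each prediction is unsatisfactory."""
        X = features[list(self.feature_names)].to_numpy(float)
        if self.kind == "logistic":
            z = self.intercept + X @ self.coef
            return 1.0 / (1.0 + np.exp(-z))
        if isinstance(self.booster, xgb.Booster):
            return self.booster.predict(xgb.DMatrix(X))
        return self.booster.predict_proba(X)[:, 1]

    def save_booster(self, path: str | Path) -> None:
        """Serialize the boosted-tree model to the library's text format."""
        if self.kind != "gradient_boosting":
            raise ValueError("save_booster applies to gradient boosting only")
        booster = (self.booster if isinstance(self.booster, xgb.Booster)
                   else self.booster.get_booster())
        booster.save_model(str(path))

    def flag(self, features: pd.DataFrame) -> np.ndarray:
        """1 where the unreliability probability reaches the threshold."""
        return (self.predict_proba(features) >= self.p_threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        if self.kind != "logistic":
            raise ValueError("only logistic models serialize to JSON; "
                             "use save_booster for gradient boosting")
        Path(path).write_text(json.dumps({
            "format_version": 1,
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "p_threshold": self.p_threshold,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "coef": self.coef.tolist(),
            "stderr": self.stderr.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetaClassifier":
        obj = json.loads(Path(path).read_text())
        return cls(
            kind=obj["kind"],
            feature_names=tuple(obj["feature_names"]),
            p_threshold=obj["p_threshold"],
            intercept=obj["intercept"],
            intercept_se=obj["intercept_se"],
            coef=np.array(obj["coef"]),
            stderr=np.array(obj["stderr"]),
        )


def _check_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the labels")


def fit_logistic(
    features: pd.DataFrame,
    labels: Sequence[int],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> MetaClassifier:
    """Unregularized maximum-likelihood logistic regression.

    Coefficients stay on the raw feature scales (no standardization),
    and standard errors come from the inverse observed information.

    Raises
    ------
    ValueError
        If only one class is present or the classes are perfectly
        separable (the MLE then diverges).
    """
    y = np.asarray(labels, int)
    _check_classes(y)
    X = sm.add_constant(features.to_numpy(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError(
            "logistic fit produced non-finite standard errors "
            "(likely perfect separation)"
        )
    return MetaClassifier(
        kind="logistic",
        feature_names=tuple(features.columns),
        p_threshold=p_threshold,
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        coef=res.params[1:].copy(),
        stderr=res.bse[1:].copy(),
    )


def fit_gradient_boosting(
    features: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> MetaClassifier:
    """Gradient-boosting meta-model with the standard defaults.

    100 trees of depth 3 with learning rate 0.1; feature importance is
    the average gain over the splits using each feature.
    """
    y = np.asarray(labels, int)
    _check_classes(y)
    model = xgb.XGBClassifier(
        max_depth=3, learning_rate=0.1, n_estimators=100,
        random_state=seed, n_jobs=1, eval_metric="logloss",
    )
    model.fit(features.to_numpy(float), y)
    raw = model.get_booster().get_score(importance_type="gain")
    names = tuple(features.columns)
    gain = {name: float(raw.get(f"f{i}", 0.0)) for i, name in enumerate(names)}
    return MetaClassifier(
        kind="gradient_boosting", feature_names=names,
        p_threshold=p_threshold, booster=model, gain_importance=gain,
    )


# ---------------------------------------------------------------------------
# evaluation


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties 0.5)."""
    y = np.asarray(labels, int)
    _check_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, float)))


@dataclass
class EvaluationReport:
    """Confusion counts, derived metrics, and curves for one classifier."""

    tp: int
    tn: int
    fp: int
    fn: int
    roc_auc: float
    f1: float
    precision: float
    recall: float
    accuracy: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_counts(
        cls, tp: int, tn: int, fp: int, fn: int, auc: float = float("nan")
    ) -> "EvaluationReport":
        """Derive the scalar metrics from a confusion matrix alone."""
        if min(tp, tn, fp, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        accuracy = (tp + tn) / (tp + tn + fp + fn)
        return cls(tp, tn, fp, fn, auc, f1, precision, recall, accuracy)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "roc_auc": self.roc_auc, "f1": self.f1,
            "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy,
            "roc_points": self.roc_points, "pr_points": self.pr_points,
        }, allow_nan=True))


def evaluate(
    probabilities: Sequence[float],
    labels: Sequence[int],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> EvaluationReport:
    """Score flagged-vs-true unsatisfactory labels at a threshold.

    Positive = unsatisfactory; a row is called positive when its
    probability is at or above ``p_threshold``.  Zero-denominator
    precision or recall is reported as 0 with a warning.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    pred = (p >= p_threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if tp + fp == 0 or tp + fn == 0:
        log.warning("degenerate confusion matrix: precision/recall set to 0")
    report = EvaluationReport.from_counts(tp, tn, fp, fn)
    if len(np.unique(y)) == 2:
        report.roc_auc = float(roc_auc_score(y, p))
        fpr, tpr, _ = roc_curve(y, p)
        prec, rec, _ = precision_recall_curve(y, p)
        report.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        report.pr_points = list(zip(rec.tolist(), prec.tolist()))
    else:
        log.warning("single-class labels: ROC-AUC undefined")
    return report


def binned_diagnostics(
    feature_values: Sequence[float],
    abs_errors: Sequence[float],
    labels: Sequence[int],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Count, MAE, MdAE, and unsatisfactory fraction per feature bin.

    Bins are equal-width over the feature range; empty bins appear with
    count 0 so the profile is plottable as-is.
    """
    x = np.asarray(feature_values, float)
    e = np.asarray(abs_errors, float)
    y = np.asarray(labels, int)
    if x.size < n_bins:
        raise ValueError("need at least n_bins rows")
    lo, hi = x.min(), x.max()
    if lo == hi:
        edges = np.array([lo, hi])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1], right=True), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin_left": float(edges[b]),
            "bin_right": float(edges[b + 1]),
            "count": int(mask.sum()),
            "mae": float(e[mask].mean()) if mask.any() else float("nan"),
            "mdae": float(np.median(e[mask])) if mask.any() else float("nan"),
            "unsatisfactory_fraction": (
                float(y[mask].mean()) if mask.any() else float("nan")
            ),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# out-of-fold pipeline


class BaseRegressor(Protocol):
    """What the pipeline needs from a base predictive model."""

    def fit(self, train_entries: Sequence[MoleculeEntry], seed: int) -> object:
        """Train one ensemble member and return the fitted model."""

    def predict(self, model: object, smiles: Sequence[str]) -> np.ndarray:
        """Predict the property for each SMILES."""


def crossval_predictions(
    entries: Sequence[MoleculeEntry],
    base: BaseRegressor,
    n_folds: int = 5,
    m_models: int = 4,
    seed: int = 0,
) -> list[MoleculeEntry]:
    """Fill ``model_preds`` with out-of-fold ensemble-member predictions.

    Folds are molecule-level (all records of a structure share a fold);
    each molecule is predicted only by models never trained on it.
    """
    if m_models < 2:
        raise ValueError("an ensemble needs at least 2 models")
    with_folds = assign_folds(entries, n_folds, seed)
    out: list[MoleculeEntry] = []
    for f, train, test in iter_fold_splits(with_folds):
        models = [base.fit(train, seed * 1000 + f * m_models + j)
                  for j in range(m_models)]
        smiles = [e.smiles for e in test]
        preds = np.column_stack([base.predict(m, smiles) for m in models])
        for i, e in enumerate(test):
            out.append(replace(e, model_preds=tuple(float(v) for v in preds[i])))
    order = {e.smiles: i for i, e in enumerate(with_folds)}
    out.sort(key=lambda e: order[e.smiles])
    return out


def build_features_crossval(
    entries: Sequence[MoleculeEntry],
    n_folds: int = 5,
    seed: int = 0,
    k: int = cl.DEFAULT_K,
    include_mcs: bool = False,
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """UE feature table where every row is scored out-of-fold.

    Entries must already carry out-of-fold model predictions.  For each
    fold, the scaler, PCA, clusters, cluster error statistics, and
    similarity reference are fit on the other folds only, then applied
    to the fold's molecules, so no feature leaks the query's own error.
    """
    if any(not e.model_preds for e in entries):
        raise ValueError("entries must carry model predictions")
    if all(e.fold_id is None for e in entries):
        entries = assign_folds(entries, n_folds, seed)
    cache: dict[str, np.ndarray] = {}
    parts = []
    for f, train, test in iter_fold_splits(entries):
        train_err = [
            abs(ens.ensemble_prediction(e.model_preds, weights) - e.y_true)
            for e in train
        ]
        signed = [
            ens.ensemble_prediction(e.model_preds, weights) - e.y_true
            for e in train
        ]
        state = fit_feature_state(
            [e.smiles for e in train], train_err, k=k, seed=seed,
            descriptor_cache=cache, signed_errors=signed,
            y_true=[e.y_true for e in train],
        )
        parts.append(compute_ue_features(
            test, state, include_mcs=include_mcs, weights=weights,
            descriptor_cache=cache,
        ))
    df = pd.concat(parts, ignore_index=True)
    order = {e.smiles: i for i, e in enumerate(entries)}
    return df.sort_values(by="smiles", key=lambda s: s.map(order),
                          ignore_index=True)


def crossval_pipeline(
    entries: Sequence[MoleculeEntry],
    base: BaseRegressor,
    n_folds: int = 5,
    m_models: int = 4,
    seed: int = 0,
    k: int = cl.DEFAULT_K,
    include_mcs: bool = False,
) -> tuple[list[MoleculeEntry], pd.DataFrame]:
    """End-to-end out-of-fold run: base ensembles, then UE features.

    Returns the prediction table (entries with out-of-fold ensemble
    predictions) and the UE feature table, both deterministic given the
    seed.
    """
    filled = crossval_predictions(entries, base, n_folds, m_models, seed)
    ue = build_features_crossval(filled, n_folds=n_folds, seed=seed, k=k,
                                 include_mcs=include_mcs)
    return filled, ue
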