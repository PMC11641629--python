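"""k-means chemical-space clustering and cluster-derived features.

Molecules are clustered in the principal-component space with k-means
(Euclidean metric, 20 clusters by default).  Per-cluster error
statistics of the base predictive model — MAE_cl, MdAE_cl, and
optionally the mean percentage error — become uncertainty features, as
does the molecule's distance to its centroid normalized by the
cluster's mean member distance (D_cl).  Molecules far from every
centroid are effectively outliers in chemical space, and their
predictions tend to be less reliable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

DEFAULT_K = 20
FORMAT_VERSION = 1


@dataclass
class ClusterModel:
    """Fitted k-means centroids with per-cluster statistics.

    ``d_mean`` is the average member-to-centroid distance of the
    fitting set; ``mae``/``mdae``/``mpe`` hold the per-cluster error
    statistics of the base model once attached.
    """

    centroids: np.ndarray
    counts: np.ndarray
    d_mean: np.ndarray
    seed: int
    mae: np.ndarray | None = None
    mdae: np.ndarray | None = None
    mpe: np.ndarray | None = None
    inertia: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float)
        self.counts = np.asarray(self.counts, int)
        self.d_mean = np.asarray(self.d_mean, float)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "format_version": FORMAT_VERSION,
            "kind": "cluster_model",
            "k": self.k,
            "seed": self.seed,
            "centroids": self.centroids.tolist(),
            "counts": self.counts.tolist(),
            "d_mean": self.d_mean.tolist(),
            "inertia": self.inertia,
            "mae": None if self.mae is None else self.mae.tolist(),
            "mdae": None if self.mdae is None else self.mdae.tolist(),
            "mpe": None if self.mpe is None else self.mpe.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        obj = json.loads(Path(path).read_text())
        model = cls(
            np.array(obj["centroids"]), np.array(obj["counts"]),
            np.array(obj["d_mean"]), obj["seed"],
            inertia=obj.get("inertia", float("nan")),
        )
        for key in ("mae", "mdae", "mpe"):
            if obj.get(key) is not None:
                setattr(model, key, np.array(obj[key]))
        return model


def fit_kmeans(
    pc_matrix: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    Deterministic given the seed; the within-cluster sum of squares of
    the returned model is the best over all restarts.
    """
    X = np.asarray(pc_matrix, float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot fit {k} clusters on {n} points")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed, algorithm="lloyd",
    )
    labels = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    counts = np.bincount(labels, minlength=k)
    d_mean = np.zeros(k)
    for c in range(k):
        if counts[c]:
            d_mean[c] = dists[labels == c].mean()
    return ClusterModel(km.cluster_centers_, counts, d_mean, seed,
                        inertia=float(km.inertia_))


def assign_cluster(
    pc_vector: np.ndarray, model: ClusterModel
) -> tuple[int, float, float]:
    """Nearest centroid, centroid distance D, and normalized ratio D_cl.

    Ties are broken toward the lowest cluster index.  D_cl = D / D_mean
    of the assigned cluster; a degenerate cluster with D_mean = 0
    yields D_cl = 0 when D = 0 and ``inf`` otherwise.
    """
    v = np.asarray(pc_vector, float)
    if v.shape[0] != model.centroids.shape[1]:
        raise ValueError("PC vector length does not match the model")
    d = np.linalg.norm(model.centroids - v, axis=1)
    cid = int(np.argmin(d))  # argmin takes the first (lowest) index on ties
    dist = float(d[cid])
    dm = model.d_mean[cid]
    if dm > 0:
        ratio = dist / dm
    else:
        ratio = 0.0 if dist == 0.0 else float("inf")
    return cid, dist, ratio


def assign_clusters(
    pc_matrix: np.ndarray, model: ClusterModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`assign_cluster` over rows."""
    X = np.asarray(pc_matrix, float)
    d = np.linalg.norm(X[:, None, :] - model.centroids[None, :, :], axis=2)
    cids = d.argmin(axis=1)
    dists = d[np.arange(len(X)), cids]
    dm = model.d_mean[cids]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(dm > 0, dists / np.where(dm > 0, dm, 1.0),
                          np.where(dists == 0.0, 0.0, np.inf))
    return cids, dists, ratios


def cluster_error_stats(
    model: ClusterModel,
    assignments: Sequence[int],
    abs_errors: Sequence[float],
    signed_errors: Sequence[float] | None = None,
    y_true: Sequence[float] | None = None,
) -> ClusterModel:
    """Attach per-cluster MAE/MdAE (and optionally MPE) to the model.

    Statistics must come from training-fold molecules only, so the
    cluster features carry no information about the query's own error.
    Clusters without any training member fall back to the global
    MAE/MdAE with a logged warning.
    """
    a = np.asarray(assignments, int)
    e = np.asarray(abs_errors, float)
    if a.size == 0 or a.size != e.size:
        raise ValueError("assignments and abs_errors must align and be non-empty")
    global_mae = float(e.mean())
    global_mdae = float(np.median(e))
    mae = np.full(model.k, global_mae)
    mdae = np.full(model.k, global_mdae)
    mpe = None
    if signed_errors is not None and y_true is not None:
        se = np.asarray(signed_errors, float)
        yt = np.asarray(y_true, float)
        mpe = np.zeros(model.k)
    for c in range(model.k):
        mask = a == c
        if not mask.any():
            log.warning("cluster %d has no training members; using global stats", c)
            continue
        mae[c] = float(e[mask].mean())
        mdae[c] = float(np.median(e[mask]))
        if mpe is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                mpe[c] = float(np.mean(100.0 * se[mask] / yt[mask]))
    model.mae = mae
    model.mdae = mdae
    model.mpe = mpe
    return model


def distance_quartile_profile(
    model: ClusterModel,
    assignments: Sequence[int],
    distances: Sequence[float],
    abs_errors: Sequence[float],
) -> dict[int, list[float]]:
    """Per-cluster MAE by centroid-distance quartile.

    Members of each cluster are split at the empirical 25/50/75th
    percentiles of their centroid distances and the MAE is reported per
    quartile.  Clusters with fewer than 4 members are skipped with a
    warning.
    """
    a = np.asarray(assignments, int)
    d = np.asarray(distances, float)
    e = np.asarray(abs_errors, float)
    profile: dict[int, list[float]] = {}
    for c in range(model.k):
        mask = a == c
        if mask.sum() < 4:
            log.warning("cluster %d has fewer than 4 members; skipped", c)
            continue
        dc, ec = d[mask], e[mask]
        qs = np.percentile(dc, [25, 50, 75])
        bins = np.digitize(dc, qs, right=True)
        profile[c] = [float(ec[bins == q].mean()) if (bins == q).any()
                      else float("nan") for q in range(4)]
    return profile
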