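"""Molecular descriptors, scaling, count fingerprints, and PCA.

The chemical-space representation behind both the Euclidean similarity
feature and the k-means clustering is the same: real-valued 1D/2D
topological descriptors (including the functional-group counters of the
descriptor set), min-max scaled to [0, 1] on the fitting set, then
projected onto the leading principal components (20 by default).
Count fingerprints (circular environments, radius 3, folded to 8192
positions) feed the Tanimoto and cosine similarity measures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from sklearn.decomposition import PCA

from .io import SmilesParseError

log = logging.getLogger(__name__)

FINGERPRINT_LENGTH = 8192
FINGERPRINT_RADIUS = 3

FORMAT_VERSION = 1

#: Names of the 2D descriptors computed for every molecule, in column order.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    name for name, _fn in Descriptors.descList
)
_DESCRIPTOR_FNS = dict(Descriptors.descList)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_LENGTH
)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


@dataclass
class DescriptorMatrix:
    """n × d matrix of real-valued molecular descriptors."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match descriptor names")


def compute_descriptors(smiles_list: Sequence[str]) -> DescriptorMatrix:
    """Compute the full 2D descriptor set for each molecule.

    Descriptor evaluations that fail or return a non-finite value are
    imputed to 0 and logged; the column order is fixed by
    :data:`DESCRIPTOR_NAMES` and identical across calls.
    """
    RDLogger.DisableLog("rdApp.warning")
    try:
        rows = np.zeros((len(smiles_list), len(DESCRIPTOR_NAMES)))
        for i, smiles in enumerate(smiles_list):
            mol = _mol_from_smiles(smiles)
            for j, name in enumerate(DESCRIPTOR_NAMES):
                try:
                    v = _DESCRIPTOR_FNS[name](mol)
                except Exception:  # descriptor-specific failures
                    log.warning("descriptor %s failed for %s; imputing 0",
                                name, smiles)
                    v = 0.0
                if not np.isfinite(v):
                    log.warning("descriptor %s non-finite for %s; imputing 0",
                                name, smiles)
                    v = 0.0
                rows[i, j] = v
    finally:
        RDLogger.EnableLog("rdApp.warning")
    return DescriptorMatrix(rows, DESCRIPTOR_NAMES)


@dataclass
class ScalerParams:
    """Per-descriptor min and max learned from the fitting set.

    Constant descriptors (max == min) are flagged and map to 0.
    Out-of-sample values are deliberately NOT clipped to [0, 1], so the
    Euclidean geometry stays meaningful for outliers.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaler parameters")

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "format_version": FORMAT_VERSION,
            "kind": "minmax_scaler",
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["mins"]), np.array(obj["maxs"]))


def fit_scaler(matrix: DescriptorMatrix | np.ndarray) -> ScalerParams:
    """Learn per-column min/max from the fitting set."""
    X = matrix.values if isinstance(matrix, DescriptorMatrix) else np.asarray(matrix, float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    params = ScalerParams(X.min(axis=0), X.max(axis=0))
    n_const = int(params.constant_mask.sum())
    if n_const:
        log.info("%d constant descriptor(s) will scale to 0", n_const)
    return params


def apply_scaler(
    matrix: DescriptorMatrix | np.ndarray, params: ScalerParams
) -> np.ndarray:
    """Min-max scale columns; fitting-set columns span [0, 1] exactly.

    Values outside the fitted range extrapolate linearly (e.g. 8 against
    a fitted [2, 6] range maps to 1.5).
    """
    X = matrix.values if isinstance(matrix, DescriptorMatrix) else np.asarray(matrix, float)
    span = np.where(params.constant_mask, 1.0, params.maxs - params.mins)
    out = (X - params.mins) / span
    out[:, params.constant_mask] = 0.0
    return out


@dataclass(frozen=True)
class CountFingerprint:
    """Sparse circular-environment count fingerprint.

    Positions are hashed atom environments folded into
    ``length`` slots; counts accumulate on fold collisions, i.e. the
    vector is additive (integer counts), not binary.
    """

    counts: dict[int, int]
    length: int = FINGERPRINT_LENGTH

    def __post_init__(self) -> None:
        for pos, cnt in self.counts.items():
            if not (0 <= pos < self.length):
                raise ValueError(f"fingerprint position {pos} out of range")
            if cnt < 1:
                raise ValueError(f"non-positive count at position {pos}")

    @property
    def on_positions(self) -> frozenset[int]:
        return frozenset(self.counts)


def compute_count_fingerprint(smiles: str) -> CountFingerprint:
    """Circular count fingerprint (radius 3, folded to 8192 positions)."""
    mol = _mol_from_smiles(smiles)
    fp = _MORGAN.GetCountFingerprint(mol)
    return CountFingerprint(
        {int(k): int(v) for k, v in fp.GetNonzeroElements().items()}
    )


@dataclass
class PCAProjection:
    """Principal-component projection of the scaled descriptor space.

    ``loadings`` is d × c with orthonormal columns; component signs
    follow the convention that the largest-magnitude loading entry of
    each component is positive, which makes runs reproducible.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.loadings = np.asarray(self.loadings, float)
        self.explained_variance = np.asarray(self.explained_variance, float)
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loading columns are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "format_version": FORMAT_VERSION,
            "kind": "pca_projection",
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAProjection":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["mean"]), np.array(obj["loadings"]),
                   np.array(obj["explained_variance"]))


def fit_pca(
    scaled_matrix: np.ndarray, c_max: int = 20
) -> PCAProjection:
    """Fit a PCA retaining ``min(c_max, d, n - 1)`` components."""
    X = np.asarray(scaled_matrix, float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    c = min(c_max, d, n - 1)
    pca = PCA(n_components=c, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()  # d x c
    # sign convention: largest-magnitude loading entry positive
    for j in range(c):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCAProjection(pca.mean_, loadings, pca.explained_variance_)


def project(matrix: np.ndarray, pca: PCAProjection) -> np.ndarray:
    """Project scaled descriptor rows onto the retained components."""
    X = np.asarray(matrix, float)
    return (X - pca.mean) @ pca.loadings
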