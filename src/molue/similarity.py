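"""Molecular similarity measures and nearest-training-set features.

Four measures are supported: Tanimoto similarity of (binarized) count
fingerprints, cosine similarity of the raw counts, Euclidean distance
between principal-component vectors of the descriptor space, and the
maximum-common-substructure (MCS) similarity
``S = X / (A + B - X)`` where X, A, B count atoms plus bonds in the MCS
and in each of the two molecules.

For a query molecule the nearest-training-set feature is the best value
of the measure over the whole reference set: a maximum for Tanimoto,
cosine, and MCS similarity (``S_max,t``, ``S_max,c``, ``S_max,mcs``)
and a minimum for the Euclidean distance (``S_max,e``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS
from scipy.spatial.distance import cdist

from .features import CountFingerprint, compute_count_fingerprint
from .io import SmilesParseError

log = logging.getLogger(__name__)

Measure = Literal["tanimoto", "cosine", "euclidean", "mcs"]

MCS_TIMEOUT_S = 10


@dataclass
class SimilarityReference:
    """Aligned training-set views: SMILES, fingerprints, PC vectors."""

    smiles: list[str]
    fingerprints: list[CountFingerprint]
    pc_vectors: np.ndarray

    def __post_init__(self) -> None:
        self.pc_vectors = np.asarray(self.pc_vectors, float)
        n = len(self.smiles)
        if n == 0:
            raise ValueError("similarity reference must be non-empty")
        if len(self.fingerprints) != n or self.pc_vectors.shape[0] != n:
            raise ValueError("reference sequences are not aligned")

    def __len__(self) -> int:
        return len(self.smiles)


def tanimoto(fp_a: CountFingerprint, fp_b: CountFingerprint) -> float:
    """Tanimoto similarity on the binarized on-sets.

    Counts are reduced to presence/absence; two empty fingerprints give
    0 by convention.
    """
    if fp_a.length != fp_b.length:
        raise ValueError("fingerprint length mismatch")
    a, b = fp_a.on_positions, fp_b.on_positions
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def cosine_counts(fp_a: CountFingerprint, fp_b: CountFingerprint) -> float:
    """Cosine similarity on the raw (additive) counts."""
    if fp_a.length != fp_b.length:
        raise ValueError("fingerprint length mismatch")
    na = math.sqrt(sum(v * v for v in fp_a.counts.values()))
    nb = math.sqrt(sum(v * v for v in fp_b.counts.values()))
    if na == 0.0 or nb == 0.0:
        log.warning("cosine similarity against a zero fingerprint; returning 0")
        return 0.0
    dot = sum(v * fp_b.counts.get(k, 0) for k, v in fp_a.counts.items())
    return dot / (na * nb)


def euclidean_distance(pc_a: np.ndarray, pc_b: np.ndarray) -> float:
    """L2 distance between two principal-component vectors."""
    a = np.asarray(pc_a, float)
    b = np.asarray(pc_b, float)
    if a.shape != b.shape:
        raise ValueError("PC vector length mismatch")
    return float(np.linalg.norm(a - b))


@dataclass(frozen=True)
class MCSResult:
    """Maximum-common-substructure sizes and derived similarity."""

    x: int  # atoms + bonds in the MCS
    a: int  # atoms + bonds in molecule A
    b: int  # atoms + bonds in molecule B
    similarity: float
    timed_out: bool = False
    smarts: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.a, self.b)):
            raise ValueError("MCS size exceeds a molecule size")


class _AromaticElementCompare(rdFMCS.MCSAtomCompare):
    """Atoms match iff same element and same aromaticity flag."""

    def __call__(self, parameters, mol1, atom1, mol2, atom2):  # noqa: D102
        x = mol1.GetAtomWithIdx(atom1)
        y = mol2.GetAtomWithIdx(atom2)
        if x.GetAtomicNum() != y.GetAtomicNum():
            return False
        return x.GetIsAromatic() == y.GetIsAromatic()


def mcs_similarity(
    smiles_a: str, smiles_b: str, timeout_s: float = MCS_TIMEOUT_S
) -> MCSResult:
    """Connected-MCS similarity ``S = X / (A + B - X)``.

    Matching rules: equal element, aromatic atoms only match aromatic
    atoms, bond orders must agree, and ring bonds only match ring
    bonds.  Atom and bond counts are heavy-atom counts.  If the search
    exceeds ``timeout_s`` the best substructure found so far is used
    and the result is flagged ``timed_out``.
    """
    mol_a = Chem.MolFromSmiles(smiles_a)
    mol_b = Chem.MolFromSmiles(smiles_b)
    if mol_a is None:
        raise SmilesParseError(smiles_a)
    if mol_b is None:
        raise SmilesParseError(smiles_b)
    params = rdFMCS.MCSParameters()
    params.AtomTyper = _AromaticElementCompare()
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.BondCompareParameters.RingMatchesRingOnly = True
    params.BondCompareParameters.CompleteRingsOnly = False
    params.Timeout = max(1, int(round(timeout_s)))
    res = rdFMCS.FindMCS([mol_a, mol_b], params)
    x = res.numAtoms + res.numBonds
    a = mol_a.GetNumAtoms() + mol_a.GetNumBonds()
    b = mol_b.GetNumAtoms() + mol_b.GetNumBonds()
    s = x / (a + b - x) if (a + b - x) > 0 else 0.0
    if res.canceled:
        log.warning("MCS search timed out for %s vs %s; using best-so-far",
                    smiles_a, smiles_b)
    return MCSResult(x, a, b, s, bool(res.canceled), res.smartsString)


@dataclass
class QueryFeatures:
    """Per-query inputs for the nearest-training-set scan."""

    smiles: str
    fingerprint: CountFingerprint | None = None
    pc_vector: np.ndarray | None = None


def nearest_similarity(
    query: QueryFeatures,
    ref: SimilarityReference,
    measure: Measure,
    exclude_self: bool = False,
    mcs_timeout_s: float = MCS_TIMEOUT_S,
) -> float:
    """Best similarity (or smallest distance) to the reference set.

    A plain linear scan over the reference: the maximum of the measure
    for Tanimoto/cosine/MCS, the minimum distance for Euclidean.  With
    ``exclude_self`` set, reference molecules whose SMILES equals the
    query's are skipped.
    """
    idx = range(len(ref))
    if exclude_self:
        idx = [i for i in idx if ref.smiles[i] != query.smiles]
        if not idx:
            raise ValueError("reference is empty after excluding the query")
    if measure == "euclidean":
        if query.pc_vector is None:
            raise ValueError("euclidean measure requires a PC vector")
        vecs = ref.pc_vectors[list(idx)]
        d = cdist(np.asarray(query.pc_vector, float)[None, :], vecs)
        return float(d.min())
    if measure == "tanimoto":
        if query.fingerprint is None:
            raise ValueError("tanimoto measure requires a fingerprint")
        return max(tanimoto(query.fingerprint, ref.fingerprints[i]) for i in idx)
    if measure == "cosine":
        if query.fingerprint is None:
            raise ValueError("cosine measure requires a fingerprint")
        return max(
            cosine_counts(query.fingerprint, ref.fingerprints[i]) for i in idx
        )
    if measure == "mcs":
        return max(
            mcs_similarity(query.smiles, ref.smiles[i], mcs_timeout_s).similarity
            for i in idx
        )
    raise ValueError(f"unknown measure {measure!r}")


def build_reference(
    smiles: Sequence[str], pc_vectors: np.ndarray
) -> SimilarityReference:
    """Assemble a :class:`SimilarityReference` (fingerprints computed here)."""
    fps = [compute_count_fingerprint(s) for s in smiles]
    return SimilarityReference(list(smiles), fps, pc_vectors)
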