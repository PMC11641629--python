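"""Synthetic molecule libraries and simulated prediction ensembles.

Real benchmark data for retention-index, retention-time, and
collision-cross-section prediction are large and partly proprietary,
so this module generates small stand-ins with the statistical
structure the uncertainty-estimation method assumes:

* a combinatorial library of valid, filter-passing small molecules
  (alkanes, alcohols, ethers, amines, halides, ketones, esters,
  nitriles, and substituted aromatics);
* a smooth "true" property driven by molecular size and composition;
* ensembles whose signed errors are Laplace-tailed (so absolute errors
  are exponential-tailed, matching what is observed for real
  property-prediction ensembles), with a per-molecule latent
  difficulty scaling the error magnitude, a correlated-bias component
  shared by all ensemble members, and independent per-model noise.

The latent difficulty can be tied to chemical rarity (sparse regions
of descriptor space), which couples the similarity and cluster
features to the error the way the method assumes for real data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import features as ft
from .io import MoleculeEntry, standardize_smiles, supported_reason

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated prediction ensemble.

    ``s0`` is the base error scale in property units; the per-molecule
    scale is ``s0 * exp(gamma * u)`` with latent difficulty
    ``u ~ Uniform(0, 1)``.  ``kappa`` is the share of the scale that
    goes into a bias shared by all ensemble members (the part averaging
    cannot remove); ``1 - kappa`` drives independent per-model noise.
    """

    n_molecules: int = 500
    m_models: int = 4
    seed: int = 0
    s0: float = 30.0
    gamma: float = 2.0
    kappa: float = 0.3
    tail: str = "laplace"

    def __post_init__(self) -> None:
        if self.m_models < 2:
            raise ValueError("an ensemble needs at least 2 models")
        if self.s0 < 0 or self.gamma < 0:
            raise ValueError("scales must be non-negative")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.tail not in ("laplace", "normal"):
            raise ValueError("tail must be 'laplace' or 'normal'")

    @property
    def tau(self) -> float:
        return 1.0 - self.kappa


def _library_candidates() -> list[str]:
    chains = ["C" * k for k in range(1, 13)]
    branched = [
        "C" * p + f"({b})" + "C" * (length - p)
        for length in range(4, 10)
        for p in range(2, length)
        for b in ("C", "CC")
    ]
    skeletons = ["C" * k for k in range(2, 11)] + branched
    terminal = [s + g for s in skeletons
                for g in ("O", "N", "Cl", "Br", "F", "I")]
    ethers = ["C" * a + "O" + "C" * b
              for a, b in itertools.product(range(1, 7), range(1, 7))]
    ketones = ["C" * a + "C(=O)" + "C" * b
               for a, b in itertools.product(range(1, 6), range(1, 6))]
    esters = ["C" * a + "C(=O)O" + "C" * b
              for a, b in itertools.product(range(1, 6), range(1, 6))]
    nitriles = ["C" * k + "C#N" for k in range(1, 11)]
    subs = ["C", "CC", "CCC", "C(C)C", "O", "OC", "N", "Cl", "F", "Br"]
    aromatics = [f"{s}c1ccccc1" for s in subs]
    aromatics += [f"{x}c1ccc({y})cc1" for x, y in itertools.product(subs, subs)]
    aromatics += [f"{x}c1cccc({y})c1" for x, y in itertools.product(subs, subs)]
    aromatics += [f"{x}c1ccccc1{y}" for x, y in itertools.product(subs, subs)]
    aromatics += [f"{s}c1ccncc1" for s in subs]
    aromatics += [f"{s}c1cccs1" for s in subs]
    aromatics += [f"{s}c1ccc2ccccc2c1" for s in subs]
    return (chains + branched + terminal + ethers + ketones + esters
            + nitriles + aromatics)


def library_capacity() -> int:
    """Number of distinct molecules the library can produce."""
    return len(_full_library())


_LIBRARY_CACHE: list[str] | None = None


def _full_library() -> list[str]:
    global _LIBRARY_CACHE
    if _LIBRARY_CACHE is None:
        seen: dict[str, None] = {}
        for raw in _library_candidates():
            can = standardize_smiles(raw)
            if supported_reason(can) is None:
                seen.setdefault(can, None)
        _LIBRARY_CACHE = sorted(seen)
    return _LIBRARY_CACHE


def generate_molecule_library(n: int, seed: int) -> list[str]:
    """Draw ``n`` unique, valid, filter-passing canonical SMILES.

    Deterministic given the seed.  Raises if ``n`` exceeds the
    combinatorial capacity of the library.
    """
    lib = _full_library()
    if n > len(lib):
        raise ValueError(
            f"requested {n} molecules but the library holds {len(lib)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lib), size=n, replace=False)
    return [lib[i] for i in idx]


def simulate_true_property(
    smiles_list: Sequence[str],
    seed: int,
    a: float = 80.0,
    b: float = 40.0,
    intercept: float = 200.0,
    noise: float = 15.0,
) -> np.ndarray:
    """Smooth positive stand-in for a retention-like property.

    ``y = intercept + a * heavy_atoms + b * heteroatoms + ring bonus +
    Gaussian noise``; larger molecules get larger values, as retention
    measures do.
    """
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    y = np.empty(len(smiles_list))
    for i, s in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(s)
        heavy = mol.GetNumAtoms()
        hetero = sum(1 for at in mol.GetAtoms() if at.GetAtomicNum() != 6)
        rings = mol.GetRingInfo().NumRings()
        y[i] = (intercept + a * heavy + b * hetero + 60.0 * rings
                + rng.normal(0.0, noise))
    return np.maximum(y, 1.0)


def chemical_difficulty(
    smiles_list: Sequence[str],
    mix: float = 0.7,
    seed: int = 0,
    n_neighbors: int = 5,
) -> np.ndarray:
    """Latent difficulty tied to chemical rarity.

    Rarity is the distance to the ``n_neighbors``-th nearest neighbor
    in descriptor PC space (sparser regions are rarer, hence harder);
    the returned difficulty is the rank mixture
    ``mix * rarity + (1 - mix) * uniform noise``, re-ranked to a
    uniform margin on (0, 1).
    """
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    desc = ft.compute_descriptors(smiles_list)
    scaler = ft.fit_scaler(desc)
    pcs = ft.project(ft.apply_scaler(desc, scaler), ft.fit_pca(
        ft.apply_scaler(desc, scaler)))
    d = cdist(pcs, pcs)
    np.fill_diagonal(d, np.inf)
    kth = np.sort(d, axis=1)[:, min(n_neighbors, len(smiles_list) - 1) - 1]
    n = len(smiles_list)
    rarity_rank = np.argsort(np.argsort(kth)) / max(n - 1, 1)
    rng = np.random.default_rng(seed)
    raw = mix * rarity_rank + (1.0 - mix) * rng.uniform(size=n)
    return (np.argsort(np.argsort(raw)) + 0.5) / n


def simulate_ensemble(
    y_true: Sequence[float],
    config: SimulationConfig,
    difficulty: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-model predictions with difficulty-scaled errors.

    Per molecule i: scale ``s_i = s0 * exp(gamma * u_i)``; one bias
    ``b_i ~ tail(0, kappa * s_i)`` shared by all models; independent
    ``e_ij ~ tail(0, tau * s_i)`` per model; prediction
    ``p_ij = y_i + b_i + e_ij``.  Returns the n × m prediction matrix
    and the latent difficulties for recovery tests.
    """
    y = np.asarray(y_true, float)
    rng = np.random.default_rng(config.seed)
    n, m = y.size, config.m_models
    if difficulty is None:
        u = rng.uniform(size=n)
    else:
        u = np.asarray(difficulty, float)
        if u.shape != y.shape:
            raise ValueError("difficulty must align with y_true")
    s = config.s0 * np.exp(config.gamma * u)

    def draw(scale: np.ndarray, size: tuple[int, ...]) -> np.ndarray:
        if config.tail == "laplace":
            return rng.laplace(0.0, np.broadcast_to(scale, size))
        return rng.normal(0.0, np.broadcast_to(scale, size))

    bias = draw(config.kappa * s, (n,)) if config.kappa > 0 else np.zeros(n)
    noise = (draw((config.tau * s)[:, None], (n, m))
             if config.tau > 0 else np.zeros((n, m)))
    preds = y[:, None] + bias[:, None] + noise
    return preds, u


def make_prediction_table(
    config: SimulationConfig,
    couple_chemistry: bool = True,
    mix: float = 0.7,
) -> tuple[list[MoleculeEntry], np.ndarray]:
    """Full synthetic study: library, true values, simulated ensemble.

    With ``couple_chemistry`` the latent difficulty follows chemical
    rarity, so similarity and cluster features carry signal about the
    error; without it the difficulty is pure chance and only the spread
    features are informative.
    """
    smiles = generate_molecule_library(config.n_molecules, config.seed)
    y = simulate_true_property(smiles, config.seed + 1)
    difficulty = (
        chemical_difficulty(smiles, mix=mix, seed=config.seed + 2)
        if couple_chemistry else None
    )
    preds, u = simulate_ensemble(y, config, difficulty)
    entries = [
        MoleculeEntry(s, float(yv), tuple(float(p) for p in row))
        for s, yv, row in zip(smiles, y, preds)
    ]
    return entries, u


class ToyNNRegressor:
    """Deterministic nearest-neighbor base regressor for pipeline tests.

    Predicts the property of the closest training molecule in
    descriptor PC space.  Each call to :meth:`fit` bootstraps the
    training set by removing ~10% of molecules (seed-dependent), which
    provides the ensemble diversity that bootstrapped SVR ensembles
    rely on.
    """

    drop_fraction = 0.1

    def __init__(self) -> None:
        self._cache: dict[str, np.ndarray] = {}

    def _rows(self, smiles: Sequence[str]) -> np.ndarray:
        missing = [s for s in smiles if s not in self._cache]
        if missing:
            rows = ft.compute_descriptors(missing).values
            self._cache.update(dict(zip(missing, rows)))
        return np.vstack([self._cache[s] for s in smiles])

    def fit(self, train_entries: Sequence[MoleculeEntry], seed: int) -> dict:
        if not train_entries:
            raise ValueError("empty training set")
        rng = np.random.default_rng(seed)
        n = len(train_entries)
        keep = max(1, int(round(n * (1.0 - self.drop_fraction))))
        idx = np.sort(rng.choice(n, size=keep, replace=False))
        kept = [train_entries[i] for i in idx]
        desc = self._rows([e.smiles for e in kept])
        scaler = ft.fit_scaler(desc)
        scaled = ft.apply_scaler(desc, scaler)
        pca = ft.fit_pca(scaled)
        return {
            "scaler": scaler,
            "pca": pca,
            "pcs": ft.project(scaled, pca),
            "y": np.array([e.y_true for e in kept]),
        }

    def predict(self, model: dict, smiles: Sequence[str]) -> np.ndarray:
        desc = self._rows(list(smiles))
        pcs = ft.project(ft.apply_scaler(desc, model["scaler"]), model["pca"])
        nearest = cdist(pcs, model["pcs"]).argmin(axis=1)
        return model["y"][nearest]


def toy_base_regressor() -> ToyNNRegressor:
    """Base-regressor stand-in satisfying the pipeline interface."""
    return ToyNNRegressor()
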