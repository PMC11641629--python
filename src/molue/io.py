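"""Prediction-table I/O and molecule preparation.

A prediction table is one row per molecule: a SMILES string, the
experimental property value, the predictions of the m ensemble members,
and optionally a cross-validation fold id.  Before any feature
computation the molecules are standardized (canonical SMILES with
stereochemistry stripped), filtered to the supported chemistry, and
deduplicated so that each structure appears exactly once.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

log = logging.getLogger(__name__)

#: Elements supported by the base predictive models (besides implicit H).
ALLOWED_ELEMENTS = frozenset(
    {"B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Molecules with this many SSSR rings or more are rejected.
MAX_RINGS = 10

#: SMILES strings longer than this (as given, before canonicalization)
#: are rejected.
MAX_SMILES_LENGTH = 250


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


class TableFormatError(ValueError):
    """Raised when a prediction table violates the expected CSV schema."""


@dataclass(frozen=True)
class MoleculeEntry:
    """One molecule with its experimental value and ensemble predictions.

    Parameters
    ----------
    smiles
        Canonical, stereochemistry-free SMILES string.
    y_true
        Experimental property value (retention index: unitless,
        retention time: seconds, collision cross-section: Å²).
    model_preds
        Predictions of the individual ensemble members, in model order.
    fold_id
        Cross-validation fold the molecule belongs to, or ``None``.
    """

    smiles: str
    y_true: float
    model_preds: tuple[float, ...] = field(default_factory=tuple)
    fold_id: int | None = None

    def __post_init__(self) -> None:
        vals = (self.y_true, *self.model_preds)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(
                f"non-finite value in entry for {self.smiles!r}"
            )


def standardize_smiles(raw: str) -> str:
    """Canonicalize a SMILES string with stereochemistry removed.

    Identical structures map to identical strings and the function is
    idempotent: ``standardize_smiles(standardize_smiles(s)) ==
    standardize_smiles(s)``.

    Raises
    ------
    SmilesParseError
        If ``raw`` is empty or cannot be parsed.
    """
    if not raw or not raw.strip():
        raise SmilesParseError(raw)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(raw)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def supported_reason(smiles: str) -> str | None:
    """Return the first violated support rule, or ``None`` if supported.

    Rules: fewer than 10 SSSR rings, SMILES no longer than 250
    characters, and only B, C, N, O, F, Si, P, S, Cl, Br, I (plus
    hydrogen) as elements.
    """
    if len(smiles) > MAX_SMILES_LENGTH:
        return "length"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "unparsable"
    if mol.GetRingInfo().NumRings() >= MAX_RINGS:
        return "rings"
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym != "H" and sym not in ALLOWED_ELEMENTS:
            return "element"
    return None


def filter_supported(
    entries: Sequence[MoleculeEntry],
) -> tuple[list[MoleculeEntry], list[tuple[MoleculeEntry, str]]]:
    """Split entries into supported molecules and rejects with reasons.

    Filtering is total: every entry lands in exactly one of the two
    outputs, and re-filtering the kept list is the identity.
    """
    kept: list[MoleculeEntry] = []
    rejected: list[tuple[MoleculeEntry, str]] = []
    for entry in entries:
        reason = supported_reason(entry.smiles)
        if reason is None:
            kept.append(entry)
        else:
            rejected.append((entry, reason))
    return kept, rejected


def deduplicate(
    entries: Sequence[MoleculeEntry], seed: int
) -> list[MoleculeEntry]:
    """Keep exactly one entry per canonical SMILES, chosen at random.

    Duplicate structures keep one record selected uniformly with the
    given seed; output order follows the first occurrence of each
    SMILES, so the result is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[MoleculeEntry]] = {}
    for entry in entries:
        groups.setdefault(entry.smiles, []).append(entry)
    out = []
    for smiles, group in groups.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(group[int(rng.integers(len(group)))])
    return out


def _parse_float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"non-numeric value {value!r} in row {row}, column {column!r}"
        ) from None


def load_prediction_table(
    path: str | Path,
    m_expected: int | None = None,
    standardize: bool = True,
) -> list[MoleculeEntry]:
    """Read a prediction-table CSV into :class:`MoleculeEntry` records.

    Expected header: ``smiles,y_true,pred_1..pred_m[,fold]``.  The
    250-character length rule is checked against the SMILES as written
    in the file, before canonicalization.

    Raises
    ------
    TableFormatError
        On missing columns, non-numeric cells, or an ensemble size that
        disagrees with ``m_expected``; messages carry row numbers.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if len(header) < 3 or header[0] != "smiles" or header[1] != "y_true":
            raise TableFormatError(
                f"{path}: header must start with smiles,y_true,pred_1..; "
                f"got {header!r}"
            )
        has_fold = header[-1] == "fold"
        pred_cols = header[2 : len(header) - 1 if has_fold else len(header)]
        expected_names = [f"pred_{i + 1}" for i in range(len(pred_cols))]
        if pred_cols != expected_names:
            raise TableFormatError(
                f"{path}: prediction columns must be {expected_names}, "
                f"got {pred_cols}"
            )
        m = len(pred_cols)
        if m_expected is not None and m != m_expected:
            raise TableFormatError(
                f"{path}: expected {m_expected} prediction columns, found {m}"
            )
        entries: list[MoleculeEntry] = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TableFormatError(
                    f"{path}: row {i} has {len(row)} cells, "
                    f"expected {len(header)}"
                )
            raw = row[0].strip()
            if len(raw) > MAX_SMILES_LENGTH:
                log.warning("row %d: SMILES longer than %d characters",
                            i, MAX_SMILES_LENGTH)
            smiles = standardize_smiles(raw) if standardize else raw
            y = _parse_float(row[1], i, "y_true")
            preds = tuple(
                _parse_float(row[2 + j], i, f"pred_{j + 1}") for j in range(m)
            )
            fold = None
            if has_fold:
                cell = row[-1].strip()
                if cell:
                    try:
                        fold = int(cell)
                    except ValueError:
                        raise TableFormatError(
                            f"{path}: non-integer fold {cell!r} in row {i}"
                        ) from None
            entries.append(MoleculeEntry(smiles, y, preds, fold))
    return entries


def write_prediction_table(
    entries: Sequence[MoleculeEntry], path: str | Path
) -> None:
    """Write entries to CSV with the ``load_prediction_table`` schema."""
    path = Path(path)
    if not entries:
        raise ValueError("cannot write an empty prediction table")
    m = len(entries[0].model_preds)
    has_fold = any(e.fold_id is not None for e in entries)
    header = ["smiles", "y_true"] + [f"pred_{i + 1}" for i in range(m)]
    if has_fold:
        header.append("fold")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for e in entries:
            if len(e.model_preds) != m:
                raise ValueError(
                    f"inconsistent ensemble size for {e.smiles!r}"
                )
            row = [e.smiles, repr(e.y_true)] + [repr(p) for p in e.model_preds]
            if has_fold:
                row.append("" if e.fold_id is None else str(e.fold_id))
            writer.writerow(row)


def load_reference_smiles(
    path: str | Path, standardize: bool = True
) -> list[str]:
    """Read a training-reference set of SMILES.

    Accepts either a plain-text file with one SMILES per line or a CSV
    with a ``smiles`` column.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise TableFormatError(f"{path}: empty reference file")
    lines = text.splitlines()
    first = [c.strip() for c in lines[0].split(",")]
    raws: list[str]
    if "smiles" in first:
        idx = first.index("smiles")
        raws = []
        for row in csv.reader(lines[1:]):
            if row:
                raws.append(row[idx].strip())
    else:
        raws = [ln.strip() for ln in lines if ln.strip()]
    if standardize:
        return [standardize_smiles(s) for s in raws]
    return raws


def assign_folds(
    entries: Sequence[MoleculeEntry], n_folds: int, seed: int
) -> list[MoleculeEntry]:
    """Assign molecule-level cross-validation folds.

    All entries sharing a canonical SMILES receive the same fold, so a
    molecule can never occur both in the training and test side of a
    split.  Fold sizes differ by at most one molecule.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    unique = list(dict.fromkeys(e.smiles for e in entries))
    if len(unique) < n_folds:
        raise ValueError(
            f"{len(unique)} unique molecules cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    fold_of = {unique[j]: int(i % n_folds) for i, j in enumerate(order)}
    return [replace(e, fold_id=fold_of[e.smiles]) for e in entries]


def iter_fold_splits(
    entries: Sequence[MoleculeEntry],
) -> Iterable[tuple[int, list[MoleculeEntry], list[MoleculeEntry]]]:
    """Yield ``(fold, train_entries, test_entries)`` for each fold id."""
    folds = sorted({e.fold_id for e in entries})
    if None in folds:
        raise ValueError("all entries must carry a fold id")
    for f in folds:
        train = [e for e in entries if e.fold_id != f]
        test = [e for e in entries if e.fold_id == f]
        if not test:
            raise ValueError(f"fold {f} is empty")
        yield f, train, test
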