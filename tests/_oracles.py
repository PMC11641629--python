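"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem


def _mol_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), z=atom.GetAtomicNum(),
                   arom=atom.GetIsAromatic())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=str(bond.GetBondType()), ring=bond.IsInRing())
    return g


def _node_match(a: dict, b: dict) -> bool:
    return a["z"] == b["z"] and a["arom"] == b["arom"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"] and a["ring"] == b["ring"]


def mcs_size_oracle(smiles_a: str, smiles_b: str) -> int:
    """Atoms + bonds of the maximum connected common subgraph.

    Enumerates every connected edge subset of the molecule with fewer
    bonds (plus single atoms) and checks embeddability into the other
    molecule by subgraph monomorphism under the matching rules: equal
    element, equal aromaticity, equal bond order, ring bonds only
    match ring bonds.  Exponential; intended for <= 8 heavy atoms.
    """
    ga, gb = _mol_graph(smiles_a), _mol_graph(smiles_b)
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    best = 0
    # single-atom common subgraphs
    for _, da in ga.nodes(data=True):
        if any(_node_match(da, db) for _, db in gb.nodes(data=True)):
            best = 1
            break
    edges = list(ga.edges)
    for r in range(1, len(edges) + 1):
        if 2 * r + 1 <= best:  # r bonds can give at most r+1 atoms + r bonds
            pass
        for subset in itertools.combinations(edges, r):
            h = ga.edge_subgraph(subset)
            if not nx.is_connected(h):
                continue
            size = h.number_of_nodes() + h.number_of_edges()
            if size <= best:
                continue
            gm = isomorphism.GraphMatcher(
                gb, h, node_match=_node_match, edge_match=_edge_match
            )
            if next(gm.subgraph_monomorphisms_iter(), None) is not None:
                best = size
    return best


def mcs_similarity_oracle(smiles_a: str, smiles_b: str) -> float:
    """S = X / (A + B - X) with X from :func:`mcs_size_oracle`."""
    ma = Chem.MolFromSmiles(smiles_a)
    mb = Chem.MolFromSmiles(smiles_b)
    a = ma.GetNumAtoms() + ma.GetNumBonds()
    b = mb.GetNumAtoms() + mb.GetNumBonds()
    x = mcs_size_oracle(smiles_a, smiles_b)
    return x / (a + b - x) if (a + b - x) > 0 else 0.0


def nearest_scan_oracle(values: list[float], largest: bool = True) -> float:
    """Plain O(n) scan used to cross-check nearest_similarity."""
    return max(values) if largest else min(values)


def roc_auc_oracle(scores, labels) -> float:
    """Concordance probability over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def kmeans_wcss_oracle(points, k: int) -> float:
    """Minimum within-cluster sum of squares by exhaustive partitioning."""
    import numpy as np

    pts = np.asarray(points, float)
    n = len(pts)
    best = float("inf")
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        wcss = 0.0
        for c in range(k):
            members = pts[[i for i in range(n) if assignment[i] == c]]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best
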