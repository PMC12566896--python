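"""Independent oracles used to cross-check the implementation.

Each oracle deliberately takes a different route from the code it checks:
exact rational hypergeometric enumeration for Fisher's test, greedy
from-scratch sum-of-squares minimization for Ward clustering, and a
networkx subgraph-monomorphism search on the molecular carbon graph for the
steroid scaffold.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Sums, as exact rationals, the point probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    probs = {k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
             for k in range(kmin, kmax + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def ward_merge_sequence(points: np.ndarray) -> list[frozenset]:
    """Greedy Ward merges computed from the definition.

    At each step every candidate pair of current clusters is scored by the
    increase in total within-cluster sum of squared distances to the
    centroid, recomputed from scratch; the minimizing pair merges.  Returns
    the sequence of merged leaf-index sets (the union formed at each step).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]

    def sse(idx: tuple) -> float:
        pts = points[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters: list[tuple] = [(i,) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            merged = clusters[i] + clusters[j]
            delta = sse(merged) - sse(clusters[i]) - sse(clusters[j])
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] + clusters[j]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


# the fused 6-6-6-5 all-carbon steroid skeleton as an explicit graph:
# 17 atoms, 20 bonds (14 chain bonds + 4 ring closures + 2 branch-return)
_SCAFFOLD_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8),
    (8, 9), (9, 10), (10, 11), (11, 12), (12, 13), (13, 14),
    (5, 14), (9, 14), (6, 15), (2, 15), (15, 16), (0, 16),
]


def has_steroid_skeleton(smiles: str) -> bool:
    """Subgraph-monomorphism check of the gonane skeleton, via networkx.

    Parses the molecule with RDKit (structure only) and then searches for
    the skeleton with networkx's VF2 matcher — an algorithm independent of
    RDKit's SMARTS engine.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), carbon=atom.GetAtomicNum() == 6)
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    pattern = nx.Graph(_SCAFFOLD_EDGES)
    nx.set_node_attributes(pattern, True, "carbon")
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, pattern,
        node_match=lambda n1, n2: n1["carbon"] == n2["carbon"])
    return any(True for _ in matcher.subgraph_monomorphisms_iter())
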