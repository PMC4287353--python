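"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent route available
(double loops, explicit enumeration, a reference library) and stays
independent of the code path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from fragclust import DistanceMatrix, ProteinRecord, ward_linkage
from fragclust.cluster import Dendrogram
from fragclust.seqio import STANDARD_RESIDUES


def brute_coverage(a: str, b: str, k: int = 5) -> tuple[set[int], set[int]]:
    """Quadratic double loop over every k-mer pair, exact string equality;
    windows containing X never match."""
    pos_a: set[int] = set()
    pos_b: set[int] = set()
    for i in range(len(a) - k + 1):
        fa = a[i : i + k]
        if "X" in fa:
            continue
        for j in range(len(b) - k + 1):
            if fa == b[j : j + k]:
                pos_a.update(range(i, i + k))
                pos_b.update(range(j, j + k))
    return pos_a, pos_b


def brute_lms(a: str, b: str, m, k: int = 5) -> int:
    pos_a, pos_b = brute_coverage(a, b, k)
    return sum(m.diagonal(a[i]) for i in pos_a) + sum(m.diagonal(b[j]) for j in pos_b)


def brute_distance(a: str, b: str, m, k: int = 5) -> float:
    denom = m.diagonal_sum(a) + m.diagonal_sum(b)
    if denom <= 0:
        return 1.0
    return min(1.0, max(0.0, 1.0 - brute_lms(a, b, m, k) / denom))


def ward_oracle_cophenetic(D: np.ndarray) -> np.ndarray:
    """Reference Ward-on-raw-distances cophenetic matrix via scipy.

    scipy's 'ward' applies the Lance-Williams recurrence to squared inputs
    and reports the square root, so feeding sqrt(D) and squaring the
    cophenetic heights reproduces the classic ward.D behaviour on D.
    """
    Z = linkage(squareform(np.sqrt(D)), method="ward")
    return squareform(cophenet(Z)) ** 2


def random_symmetric_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


def random_dendrogram(rng: np.random.Generator, n: int) -> Dendrogram:
    D = random_symmetric_matrix(rng, n)
    ids = tuple(f"L{i:02d}" for i in range(n))
    return ward_linkage(DistanceMatrix(ids=ids, values=D))


def random_protein(
    rng: np.random.Generator,
    pid: str,
    length: int,
    alphabet: str = STANDARD_RESIDUES,
) -> ProteinRecord:
    residues = "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
    return ProteinRecord(id=pid, residues=residues)


def tree_splits_bothsides(t: Dendrogram) -> set[frozenset[frozenset[str]]]:
    """Every non-trivial unrooted split, represented by BOTH sides (no
    reference-leaf canonicalization)."""
    sets = t.leaf_sets()
    n = t.n_leaves
    allset = frozenset(t.leaves)
    out: set[frozenset[frozenset[str]]] = set()
    for node in range(n, 2 * n - 1):
        clade = frozenset(t.leaves[i] for i in sets[node])
        comp = allset - clade
        if len(clade) >= 2 and len(comp) >= 2:
            out.add(frozenset({clade, comp}))
    return out


def oracle_rf(t1: Dendrogram, t2: Dendrogram) -> int:
    return len(tree_splits_bothsides(t1) ^ tree_splits_bothsides(t2))
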