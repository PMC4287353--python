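"""Robinson–Foulds distance between trees over the same leaf set.

Both trees are treated as unrooted: the root is suppressed and every
internal edge contributes one non-trivial bipartition of the leaves.  The
RF distance is the size of the symmetric difference of the two bipartition
sets; the normalized variant divides by 2(n−3), the maximum for two binary
trees on n leaves.

A plain set comparison of canonicalized splits is used — at the scale this
library targets, hashing schemes are an optimization, not a semantic
difference.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

from .cluster import Dendrogram

__all__ = [
    "bipartitions",
    "newick_bipartitions",
    "rf_distance",
    "normalized_rf",
    "rf_distance_newick",
]


def _canonical(
    clade: frozenset[str], all_leaves: frozenset[str], ref: str
) -> frozenset[str] | None:
    side = clade if ref not in clade else all_leaves - clade
    if 2 <= len(side) <= len(all_leaves) - 2:
        return side
    return None  # trivial split


def bipartitions(t: Dendrogram) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions of a dendrogram.

    Each split is canonicalized as the side not containing the
    lexicographically smallest leaf; the two clades under the root collapse
    to the same split, which suppresses the root.
    """
    all_leaves = frozenset(t.leaves)
    ref = min(t.leaves)
    sets = t.leaf_sets()
    n = t.n_leaves
    out: set[frozenset[str]] = set()
    for node in range(n, 2 * n - 1):
        clade = frozenset(t.leaves[i] for i in sets[node])
        side = _canonical(clade, all_leaves, ref)
        if side is not None:
            out.add(side)
    return out


def newick_bipartitions(source: str | Path) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Parse a Newick tree (string or file path) into (leaf set, splits)."""
    # A Newick string for >= 2 leaves always contains "("; anything else is a path.
    if isinstance(source, Path) or "(" not in source:
        tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = _canonical(clade, leaves, ref)
        if side is not None:
            out.add(side)
    return leaves, out


def _check_leaves(l1: frozenset[str], l2: frozenset[str]) -> None:
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise ValueError(f"trees have different leaf sets; symmetric difference: {diff}")


def rf_distance(t1: Dendrogram, t2: Dendrogram) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    _check_leaves(frozenset(t1.leaves), frozenset(t2.leaves))
    return len(bipartitions(t1) ^ bipartitions(t2))


def normalized_rf(t1: Dendrogram, t2: Dendrogram) -> float:
    """RF divided by its maximum 2(n−3) for binary trees; 0 when n ≤ 3."""
    rf = rf_distance(t1, t2)
    n = t1.n_leaves
    return rf / (2 * (n - 3)) if n > 3 else 0.0


def rf_distance_newick(source1: str | Path, source2: str | Path) -> tuple[int, float]:
    """(raw, normalized) RF between two Newick trees (strings or paths)."""
    l1, s1 = newick_bipartitions(source1)
    l2, s2 = newick_bipartitions(source2)
    _check_leaves(l1, l2)
    rf = len(s1 ^ s2)
    n = len(l1)
    return rf, (rf / (2 * (n - 3)) if n > 3 else 0.0)
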