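"""Ward agglomerative clustering, Newick export and cut-off parsing.

The linkage follows the classic "ward.D" behaviour of R's hclust: the
Lance–Williams recurrence with Ward's minimum-variance coefficients is
applied to the input dissimilarities as given (not squared),

    d(k, i∪j) = [ (n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) − n_k d(i,j) ]
                / (n_i + n_j + n_k).

Ward's criterion is reducible, so merge heights are non-decreasing and the
dendrogram has no inversions.  Ties are broken by the smallest (row, column)
pair of node indices in creation order, making the tree bit-reproducible.

Flat clusters are obtained by rescaling all merge heights by the maximum
(the root then sits at height 1) and removing every merge above a cut-off
``x`` in [0, 1]; the surviving connected components are the clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lms import DistanceMatrix


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree with heights.

    Nodes are indexed 0..n-1 for the leaves (input order) and n..2n-2 for
    the internal nodes in merge order; ``merges[t]`` = (left, right, height)
    creates node ``n + t``.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        seen_children: set[int] = set()
        prev_h = 0.0
        for t, (l, r, h) in enumerate(self.merges):
            node = n + t
            for c in (l, r):
                if not 0 <= c < node:
                    raise ValueError(f"merge {t}: child {c} out of range")
                if c in seen_children:
                    raise ValueError(f"merge {t}: node {c} merged twice")
                seen_children.add(c)
            if h < prev_h - 1e-12:
                raise ValueError(f"merge {t}: height {h} decreases")
            prev_h = max(prev_h, h)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def max_height(self) -> float:
        return max(h for _, _, h in self.merges)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def leaf_sets(self) -> list[set[int]]:
        """Leaf-index set under every node (leaves first, then internal)."""
        n = self.n_leaves
        sets: list[set[int]] = [{i} for i in range(n)]
        for l, r, _ in self.merges:
            sets.append(sets[l] | sets[r])
        return sets


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering at a cut-off: 1-based gap-free cluster labels."""

    cutoff: float
    labels: Mapping[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        found = set(self.labels.values())
        if found != set(range(1, self.n_clusters + 1)):
            raise ValueError(
                f"cluster labels {sorted(found)} are not 1..{self.n_clusters}"
            )


def ward_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate the distance matrix under Ward's criterion (ward.D).

    Deterministic: equal-criterion ties merge the pair with the smallest
    node indices in creation order.
    """
    dm.validate()
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    # Current inter-cluster distances keyed by (creation id, creation id).
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                cand = (dist[key], key[0], key[1])
                if best is None or cand < best:
                    best = cand
        h, i, j = best
        new = n + t
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dki = dist[(min(i, k), max(i, k))]
            dkj = dist[(min(j, k), max(j, k))]
            dist[(k, new)] = ((ni + nk) * dki + (nj + nk) * dkj - nk * h) / (
                ni + nj + nk
            )
        size[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
        merges.append((i, j, h))
    return Dendrogram(leaves=dm.ids, merges=tuple(merges))


def cophenetic_matrix(t: Dendrogram) -> np.ndarray:
    """n×n matrix of the merge height at which each leaf pair first joins."""
    n = t.n_leaves
    sets = t.leaf_sets()
    coph = np.zeros((n, n), dtype=float)
    for idx, (l, r, h) in enumerate(t.merges):
        for a in sets[l]:
            for b in sets[r]:
                coph[a, b] = coph[b, a] = h
    return coph


def cut_tree(t: Dendrogram, x: float) -> ClusterAssignment:
    """Parse the dendrogram at cut-off ``x`` in [0, 1].

    Heights are first rescaled by the maximum merge height so the root sits
    at 1; merges with rescaled height > x are removed and the remaining
    connected components are the clusters, numbered 1..K in order of first
    leaf appearance.  A degenerate tree whose merges are all at height 0
    collapses to a single cluster at any cut-off.
    """
    if not 0 <= x <= 1:
        raise ValueError(f"cut-off must be in [0, 1], got {x}")
    n = t.n_leaves
    maxh = t.max_height
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, (l, r, h) in enumerate(t.merges):
        keep = True if maxh == 0 else (h / maxh) <= x
        if keep:
            node = n + idx
            parent[find(l)] = node
            parent[find(r)] = node
    labels: dict[str, int] = {}
    root_to_cluster: dict[int, int] = {}
    for i, leaf in enumerate(t.leaves):
        root = find(i)
        if root not in root_to_cluster:
            root_to_cluster[root] = len(root_to_cluster) + 1
        labels[leaf] = root_to_cluster[root]
    return ClusterAssignment(cutoff=x, labels=labels, n_clusters=len(root_to_cluster))


_NEEDS_QUOTE = re.compile(r"[\s()\[\]':;,]")


def _newick_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_branch(x: float) -> str:
    return format(x, ".10g")


def to_newick(t: Dendrogram) -> str:
    """Render the dendrogram as a Newick string with branch lengths.

    A child's branch length is its parent's merge height minus its own
    height (leaves sit at height 0); labels containing whitespace or Newick
    metacharacters are single-quoted.
    """
    n = t.n_leaves

    def sub(node: int, parent_h: float) -> str:
        if node < n:
            body, h = _newick_label(t.leaves[node]), 0.0
        else:
            l, r, h = t.merges[node - n]
            body = f"({sub(l, h)},{sub(r, h)})"
        return f"{body}:{_fmt_branch(parent_h - h)}"

    l, r, h = t.merges[-1]
    return f"({sub(l, h)},{sub(r, h)});"
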