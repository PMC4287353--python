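"""Domain-architecture similarity indices and per-cluster reports.

Three indices, each in [0, 1], capture orthogonal aspects of how two
domain architectures P and Q relate:

* Jaccard index J_PQ — shared domain *types* over distinct domain types
  (content, ignoring order and copy number).
* Goodman–Kruskal gamma γ_PQ — concordance of the N→C order of shared
  domain types, rescaled from [−1, 1] to [0, 1] (order, ignoring copy
  number).
* Duplication similarity D_PQ — mean over shared types of the min/max
  copy-number ratio (copy number, ignoring order).

Within each flat cluster the three indices are averaged over all unordered
member pairs; homogeneous clusters report means near 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np

from .cluster import ClusterAssignment
from .seqio import DomainArchitecture

logger = logging.getLogger(__name__)


def jaccard_index(p: DomainArchitecture, q: DomainArchitecture) -> float:
    """Shared domain types over the union of domain types; 1 for two empty
    architectures (trivially identical)."""
    sp, sq = set(p.domains), set(q.domains)
    if not sp and not sq:
        return 1.0
    return len(sp & sq) / len(sp | sq)


def gk_gamma(p: DomainArchitecture, q: DomainArchitecture) -> float:
    """Goodman–Kruskal gamma over shared domain types, rescaled to [0, 1].

    Each unordered pair of distinct shared types is concordant (S) if the
    relative N→C order of their first occurrences agrees between P and Q,
    discordant (R) if reversed; γ = (S−R)/(S+R), returned as (γ+1)/2.
    With fewer than two shared types order conservation is vacuous → 1.
    """
    shared = set(p.domains) & set(q.domains)
    if len(shared) < 2:
        return 1.0
    first_p = {d: p.domains.index(d) for d in shared}
    first_q = {d: q.domains.index(d) for d in shared}
    s = r = 0
    for d1, d2 in combinations(sorted(shared), 2):
        same = (first_p[d1] < first_p[d2]) == (first_q[d1] < first_q[d2])
        if same:
            s += 1
        else:
            r += 1
    gamma = (s - r) / (s + r)
    return (gamma + 1) / 2


def duplication_similarity(p: DomainArchitecture, q: DomainArchitecture) -> float:
    """Mean over shared domain types of min/max occurrence-count ratio.

    0 when no type is shared; 1 for identical copy-number profiles (two
    empty architectures count as identical).
    """
    cp, cq = Counter(p.domains), Counter(q.domains)
    if not cp and not cq:
        return 1.0
    shared = set(cp) & set(cq)
    if not shared:
        return 0.0
    return float(
        np.mean([min(cp[d], cq[d]) / max(cp[d], cq[d]) for d in sorted(shared)])
    )


def pair_scores(p: DomainArchitecture, q: DomainArchitecture) -> tuple[float, float, float]:
    """(Jaccard, rescaled gamma, duplication similarity) for one pair."""
    return jaccard_index(p, q), gk_gamma(p, q), duplication_similarity(p, q)


@dataclass(frozen=True)
class ClusterReport:
    """Per-cluster membership and index statistics over member pairs.

    Means and population standard deviations are taken over every unordered
    pair of members that both carry an architecture; clusters with fewer
    than two annotated members report ``None`` (rendered ``NA``).
    """

    cluster_index: int
    members: tuple[str, ...]
    n_pairs_scored: int
    jc_mean: float | None
    jc_sd: float | None
    gk_mean: float | None
    gk_sd: float | None
    ds_mean: float | None
    ds_sd: float | None


def cluster_report(
    assignment: ClusterAssignment | Mapping[str, int],
    archs: Mapping[str, DomainArchitecture],
) -> list[ClusterReport]:
    """Aggregate the three indices over all member pairs of each cluster.

    Members without an architecture are counted and logged but skipped in
    the pair statistics.  If no cluster has two annotated members the
    report is empty (with a warning).
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    clusters: dict[int, list[str]] = {}
    for pid, idx in labels.items():
        clusters.setdefault(idx, []).append(pid)
    n_unmatched = sum(1 for pid in labels if pid not in archs)
    if n_unmatched:
        logger.info("%d clustered protein(s) lack an architecture entry", n_unmatched)

    reports: list[ClusterReport] = []
    any_scored = False
    for idx in sorted(clusters):
        members = tuple(sorted(clusters[idx]))
        annotated = [pid for pid in members if pid in archs]
        scores = [
            pair_scores(archs[a], archs[b]) for a, b in combinations(annotated, 2)
        ]
        if scores:
            any_scored = True
            arr = np.array(scores)
            means = arr.mean(axis=0)
            sds = arr.std(axis=0)  # population SD over all pairs
            reports.append(
                ClusterReport(
                    cluster_index=idx,
                    members=members,
                    n_pairs_scored=len(scores),
                    jc_mean=float(means[0]), jc_sd=float(sds[0]),
                    gk_mean=float(means[1]), gk_sd=float(sds[1]),
                    ds_mean=float(means[2]), ds_sd=float(sds[2]),
                )
            )
        else:
            reports.append(
                ClusterReport(
                    cluster_index=idx,
                    members=members,
                    n_pairs_scored=0,
                    jc_mean=None, jc_sd=None,
                    gk_mean=None, gk_sd=None,
                    ds_mean=None, ds_sd=None,
                )
            )
    if not any_scored:
        logger.warning("no cluster has >= 2 members with architectures; empty report")
        return []
    return reports


def write_cluster_report(reports: list[ClusterReport], path: str | Path) -> None:
    """Write the report TSV; undefined statistics are rendered as ``NA``."""
    cols = (
        "cluster_index", "n_members", "n_pairs_scored",
        "JC-mean", "JC-sd", "GK-mean", "GK-sd", "DS-mean", "DS-sd",
    )

    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write(
                "\t".join(
                    [
                        str(r.cluster_index),
                        str(len(r.members)),
                        str(r.n_pairs_scored),
                        fmt(r.jc_mean), fmt(r.jc_sd),
                        fmt(r.gk_mean), fmt(r.gk_sd),
                        fmt(r.ds_mean), fmt(r.ds_sd),
                    ]
                )
                + "\n"
            )
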