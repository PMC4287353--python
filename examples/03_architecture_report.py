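"""Domain-architecture similarity indices, pairwise and per cluster.

Three indices in [0, 1] compare two ordered domain lists: Jaccard (shared
domain types), Goodman-Kruskal gamma (N->C order conservation, rescaled)
and duplication similarity (copy-number agreement).  Per cluster, the
means over all member pairs summarise architectural homogeneity.
"""

from fragclust import (
    DomainArchitecture,
    cluster_report,
    duplication_similarity,
    gk_gamma,
    jaccard_index,
)

A = lambda pid, *d: DomainArchitecture(protein_id=pid, domains=d)

pairs = [
    (A("p", "Pkinase", "SH2", "SH3"), A("q", "SH2", "SH3", "PH"), "partial overlap"),
    (A("p", "A", "B", "C"), A("q", "C", "B", "A"), "same content, reversed order"),
    (A("p", "Ig", "Ig", "Fn3"), A("q", "Ig", "Fn3"), "duplicated Ig domain"),
]
for p, q, label in pairs:
    print(f"{list(p.domains)} vs {list(q.domains)}  ({label})")
    print(f"  Jaccard={jaccard_index(p, q):.4f}  "
          f"gamma={gk_gamma(p, q):.4f}  "
          f"duplication={duplication_similarity(p, q):.4f}")

# per-cluster aggregation: cluster 1 homogeneous, cluster 2 mixed
labels = {"p1": 1, "p2": 1, "p3": 2, "p4": 2}
archs = {
    "p1": A("p1", "Pkinase", "SH2"),
    "p2": A("p2", "Pkinase", "SH2"),
    "p3": A("p3", "Ig", "Ig"),
    "p4": A("p4", "PH"),
}
for rep in cluster_report(labels, archs):
    print(f"cluster {rep.cluster_index}: JC-mean={rep.jc_mean:.3f} "
          f"GK-mean={rep.gk_mean:.3f} DS-mean={rep.ds_mean:.3f} "
          f"(over {rep.n_pairs_scored} pair(s))")
print("-> reversal only lowers gamma; duplication only lowers the")
print("   copy-number index; a JC-mean of 1 marks an architecture-pure cluster.")
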