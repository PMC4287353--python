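# Methods

## Problem and model

fragclust classifies a set of full-length protein amino-acid sequences
without aligning them. The motivating regime is multi-domain proteins:
homologs that share domain content but differ in domain order (shuffling),
in copy number (duplication) or by circular permutation defeat positional
alignment, while a comparison based on the *multiset of local fragments*
is indifferent to where in the chain a conserved block sits.

### Local Matching Score and distance

Two sequences are compared through their consecutive five-residue
fragments (k-mers with k = 5). A position of either sequence is *covered*
if it lies inside at least one fragment of its own sequence that occurs
verbatim in the other. The Local Matching Score sums the BLOSUM62 diagonal
`M[r, r]` over the covered positions of both sides; the distance is

    d(s, s') = 1 − LMS(s, s') / (S(s) + S(s')),
    S(s) = Σ_i M[s_i, s_i],

clamped to [0, 1]. Rationale for this normalizer: `LMS ≤ S(s) + S(s')`
always (each side's covered sum is bounded by its full diagonal sum), so
`d ≥ 0` for X-free input; identical sequences give exactly 0; disjoint
fragment sets give exactly 1. The denominator deliberately counts *all*
positions — including those inside fragments containing the unknown
residue X, which are barred from matching — so unannotated stretches
dilute similarity rather than manufacture it.

Design choices that were genuinely open, and how they were fixed:

* **Matching is exact string equality of 5-mers.** No substitutable-residue
  expansion: exact matching keeps the engine deterministic and verifiable
  against a brute-force double loop, and at k = 5 over a 20-letter
  alphabet spurious matches are already rare.
* **Both sides are summed.** The score counts covered residues of *s* and
  of *s′*; repeated fragments therefore weight the score by how much of
  each sequence is explained, not by how many fragment pairs exist.
* **X never matches, not even X.** Any 5-mer containing X is excluded from
  the match search. X retains its standard BLOSUM62 diagonal (−1) in S(s).
  For sequences consisting almost entirely of X this can push the raw
  ratio outside [0, 1]; the clamp covers that pathological corner and is
  a no-op for ordinary input. Nonstandard letters B/Z/U/O/J are folded
  into X on read (with a warning) because the scoring contract defines a
  diagonal only for the 20 standard residues plus X.
* **Integer arithmetic** throughout the scores, with a single final
  division: distances are bit-reproducible across platforms.
* `k` is exposed as a parameter but every default is 5, the fragment
  length the method is built around.

The distance is *not* guaranteed to satisfy the triangle inequality; it is
documented as a dissimilarity, and nothing downstream (Ward clustering)
requires metricity.

## Clustering

Agglomeration follows Ward's minimum-variance criterion in its classic
"ward.D" form: the Lance–Williams update

    d(k, i∪j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) − n_k d(i,j)]
                / (n_i + n_j + n_k)

applied to the input dissimilarities as given (not squared). This matches
the long-standing behaviour of R's `hclust(..., "ward")` of the era the
pipeline descends from, rather than the later ward.D2 variant. Ward's
criterion is reducible, so heights never invert. Ties on the merge
criterion are broken toward the smallest pair of node indices in creation
order, making the dendrogram bit-reproducible; the tests verify
cophenetic equality (1e-9) against an independent reference
implementation (scipy's ward on square-rooted inputs, whose squared
heights are exactly the ward.D recurrence).

**Cut-off semantics.** Ward merge heights on [0, 1] distances routinely
exceed 1, but the user-facing cut-off x lives in [0, 1]. All heights are
divided by the maximum merge height (root at 1) before cutting; merges
with rescaled height > x are removed and the connected components are the
clusters, numbered 1..K by first leaf appearance. Consequences: x = 1 is
always one cluster; x = 0 is all singletons unless zero-height merges
exist; the cluster count is a non-increasing step function of x. A
degenerate tree whose merges are all at height 0 collapses to a single
cluster at every x. The max-height rescaling is one plausible reading of
a cut-off "between 0 and 1" against unbounded Ward heights; it is the
package's own convention and is stated here because alternatives (cutting
raw heights directly) would change which x separates families.

Newick export writes ultrametric branch lengths (child branch = parent
height − child height, leaves at height 0) and single-quotes labels
containing whitespace or Newick metacharacters.

## Architecture similarity indices

Domain architectures are user-supplied ordered lists of domain
identifiers (N→C). For a pair P, Q:

* **Jaccard** J = |shared types| / |union of types| — over domain *types*,
  not occurrences, so it measures content only; two empty architectures
  are trivially identical (J = 1).
* **Goodman–Kruskal γ** over all unordered pairs of distinct shared types,
  using each type's *first occurrence* position: S concordant + R
  discordant pairs give γ = (S−R)/(S+R), reported rescaled as (γ+1)/2.
  With fewer than two shared types order conservation is vacuous and the
  index is 1. First-occurrence positions keep γ orthogonal to copy-number
  effects, which belong to D.
* **Duplication similarity** D = mean over shared types of
  min(c_P, c_Q)/max(c_P, c_Q) on occurrence counts; 0 with no shared
  type, 1 for identical copy-number profiles. This formula is the
  package's own concrete definition of a copy-number similarity in
  [0, 1]; it is symmetric, order-invariant and 1 exactly on matching
  profiles.

Per cluster, the three indices are averaged over every unordered pair of
members that both carry architectures; standard deviations are population
SDs (divide by the number of pairs). Singleton or unannotated clusters
report NA rather than failing; if no cluster has two annotated members
the report is empty with a warning.

## Robinson–Foulds comparator

Dendrograms (or external Newick trees) are compared as *unrooted* trees:
the root is suppressed, every internal edge yields a non-trivial leaf
bipartition (canonicalized as the side not containing the
lexicographically smallest leaf), and RF is the size of the symmetric
difference of the two split sets, with a normalized variant RF / 2(n−3).
A plain set comparison is used; hashing schemes are an optimization, not
a semantic difference, at the scales this library targets (n ≤ 10⁴).

## Synthetic data generator

The generator builds datasets with known family structure to make the
whole pipeline testable without external data. Each domain type receives
one random master sequence (uniform over the 20 residues); each family is
an ordered architecture over domain types; each member is the
concatenation of its architecture's masters with i.i.d. point
substitutions (replacement uniform over the 19 other residues — the
simplest null that still erodes exact 5-mer matches at the expected
per-fragment survival rate (1−p)^10). A chosen fraction of members get a
random permutation of their domain order, and a disjoint fraction a
circular rotation; the architecture metadata follows the rearrangement.
Everything derives from one integer seed.

Defaults — the study conditions used by the tests and the acceptance
script — are: 3 families × 8 members; 7 domain types of 30–60 residues,
two private types per family plus one shared C-terminal type (the
promiscuous-domain regime); substitution rate 0.05 per residue; shuffle
fraction 0.25; circular permutation 0 by default and 0.25 in the
rearrangement checks; tree cut-off 0.55. The sizes keep the full pipeline
(24 sequences, ~300–2000 pairwise 5-mer comparisons each) under a couple
of seconds while leaving the within/between-family contrast realistic
(measured means ≈ 0.2 vs ≈ 0.76 at these settings).

**What the generator does not emulate:** indels, rate heterogeneity,
BLOSUM-biased substitution, partial domains, or real promiscuous-domain
statistics. Passing the synthetic recovery tests therefore shows that the
pipeline is correct and order-robust under point divergence of reused
blocks — not that any particular biological family will separate at
x = 0.55; on real data the informative cut-off must be chosen by the
user.

## Numerical and degenerate-input conventions

* Distances: exact integer scores, one final division, clamp to [0, 1].
* Sequences shorter than 5 residues share no fragment with anything and
  sit at distance 1 from everything (including themselves); a non-positive
  combined self-score (possible only for X-dominated input) also yields
  distance 1, with a warning.
* Ward ties: smallest creation-order index pair merges first.
* Cluster numbering: order of first leaf appearance in the input.
* RF on trees with n ≤ 3 leaves: no non-trivial splits exist, RF = 0 and
  the normalized value is defined as 0.

## Known limitations

* The LMS distance is not a metric; dendrogram heights are Ward criterion
  values, not evolutionary distances.
* Exact 5-mer matching saturates for very long, highly diverged pairs
  (both coverage sets can approach totality from unrelated repeats);
  reduced-alphabet or substitution-aware matching is out of scope.
* The O(n²) pair loop and O(n³) linkage are fine to a few thousand
  sequences; no attempt is made at the throughput of hashed or
  suffix-tree engines.
* Architecture annotation is never inferred; proteins absent from the
  architecture file are simply skipped in reports (with a logged count).
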