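"""Local Matching Score (LMS) distances between protein sequences.

The LMS is an alignment-free similarity: two sequences are compared through
their consecutive five-residue fragments.  Every position of either sequence
that lies inside at least one fragment occurring verbatim in the other
sequence is *covered*; the score sums the BLOSUM62 diagonal ``M[r, r]`` over
the covered positions of both sides,

    LMS(s, s') = sum_{i in cov(s)} M[s_i, s_i] + sum_{j in cov(s')} M[s'_j, s'_j].

Because matching is positional-order-free, the score is unaffected by domain
shuffling or circular permutation — the regimes where alignment-based
comparison of multi-domain proteins breaks down.

The similarity is turned into a distance in [0, 1] by normalizing against
the total diagonal self-score of both sequences,

    d(s, s') = 1 - LMS(s, s') / (S(s) + S(s')),   S(s) = sum_i M[s_i, s_i],

so identical X-free sequences sit at distance 0 and sequences sharing no
fragment sit at distance 1.  All sums are exact integer arithmetic until the
final division, making distances bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ALPHABET, ProteinRecord

logger = logging.getLogger(__name__)

#: Fragment length used throughout; five residues is the method's choice.
DEFAULT_K = 5


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Integer substitution scores over the 20 standard residues plus X.

    Symmetric, with a diagonal entry for every alphabet letter.  Only the
    diagonal enters the LMS; the full matrix is kept so alternative NCBI
    matrices drop in unchanged.
    """

    name: str
    entries: Mapping[tuple[str, str], int]
    _diag: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        diag = {}
        for (a, b), v in self.entries.items():
            if self.entries.get((b, a)) != v:
                raise ValueError(f"matrix {self.name!r} is not symmetric at ({a},{b})")
            if a == b:
                diag[a] = v
        missing = ALPHABET - set(diag)
        if missing:
            raise ValueError(
                f"matrix {self.name!r} lacks diagonal entries for {sorted(missing)}"
            )
        object.__setattr__(self, "_diag", diag)

    def diagonal(self, residue: str) -> int:
        try:
            return self._diag[residue]
        except KeyError:
            raise ValueError(f"no diagonal score for residue {residue!r}") from None

    def diagonal_sum(self, residues: str) -> int:
        """Sum of M[r, r] over every position of ``residues``."""
        d = self._diag
        try:
            return sum(d[r] for r in residues)
        except KeyError as exc:
            raise ValueError(f"no diagonal score for residue {exc.args[0]!r}") from None


def _from_biopython(name: str, arr) -> SubstitutionMatrix:
    letters = [ch for ch in arr.alphabet if ch in ALPHABET]
    entries = {
        (a, b): int(arr[a, b]) for a in letters for b in letters
    }
    return SubstitutionMatrix(name=name, entries=entries)


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named substitution matrix (BLOSUM62 by default)."""
    return _from_biopython(name, substitution_matrices.load(name))


def read_substitution_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read a matrix in NCBI text format from a file."""
    path = Path(path)
    return _from_biopython(path.stem, substitution_matrices.read(str(path)))


def _residues(seq: ProteinRecord | str) -> str:
    return seq.residues if isinstance(seq, ProteinRecord) else seq


def fragment_index(record: ProteinRecord | str, k: int = DEFAULT_K) -> dict[str, list[int]]:
    """Map each k-mer of the sequence to the sorted list of its start offsets.

    A sequence shorter than ``k`` yields an empty index.
    """
    if k < 1:
        raise ValueError(f"fragment length k must be >= 1, got {k}")
    res = _residues(record)
    index: dict[str, list[int]] = {}
    for o in range(len(res) - k + 1):
        index.setdefault(res[o : o + k], []).append(o)
    return index


def _coverage(
    idx_a: Mapping[str, list[int]],
    idx_b: Mapping[str, list[int]],
    k: int,
) -> tuple[set[int], set[int]]:
    # Fragments containing X never match (even another X fragment): unknown
    # residues must not manufacture similarity.
    pos_a: set[int] = set()
    pos_b: set[int] = set()
    if len(idx_a) > len(idx_b):  # iterate the smaller key set
        small, big, swap = idx_b, idx_a, True
    else:
        small, big, swap = idx_a, idx_b, False
    for kmer, offs in small.items():
        if "X" in kmer:
            continue
        other = big.get(kmer)
        if other is None:
            continue
        p_small = pos_b if swap else pos_a
        p_big = pos_a if swap else pos_b
        for o in offs:
            p_small.update(range(o, o + k))
        for o in other:
            p_big.update(range(o, o + k))
    return pos_a, pos_b


def matched_coverage(
    a: ProteinRecord | str, b: ProteinRecord | str, k: int = DEFAULT_K
) -> tuple[set[int], set[int]]:
    """Positions of each sequence covered by fragments shared with the other.

    A position belongs to the first set iff it lies inside at least one
    k-mer of ``a`` occurring verbatim somewhere in ``b``; symmetrically for
    the second set.  Both sets are empty when no k-mer is shared.
    """
    return _coverage(fragment_index(a, k), fragment_index(b, k), k)


def lms_score(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    m: SubstitutionMatrix,
    k: int = DEFAULT_K,
) -> int:
    """Local Matching Score: diagonal sums over both covered-position sets."""
    res_a, res_b = _residues(a), _residues(b)
    pos_a, pos_b = matched_coverage(res_a, res_b, k)
    return sum(m.diagonal(res_a[i]) for i in pos_a) + sum(
        m.diagonal(res_b[j]) for j in pos_b
    )


def diagonal_self_score(record: ProteinRecord | str, m: SubstitutionMatrix) -> int:
    """Full diagonal sum S(s) = sum_i M[s_i, s_i]; the normalization unit."""
    return m.diagonal_sum(_residues(record))


def pairwise_distance(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    m: SubstitutionMatrix,
    k: int = DEFAULT_K,
) -> float:
    """Normalized LMS distance in [0, 1]; 0 for identical X-free sequences,
    1 when no fragment is shared."""
    denom = diagonal_self_score(a, m) + diagonal_self_score(b, m)
    if denom <= 0:
        logger.warning(
            "non-positive combined self-score (%d); distance defined as 1", denom
        )
        return 1.0
    num = lms_score(a, b, m, k)
    # X-heavy sequences can push the ratio outside [0,1] (X never matches but
    # its diagonal is negative); clamp to keep the distance contract.
    return min(1.0, max(0.0, 1.0 - num / denom))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of normalized LMS distances, zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("distance matrix ids are not unique")

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("distance matrix entries outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def distance_matrix(
    records: Sequence[ProteinRecord],
    m: SubstitutionMatrix,
    k: int = DEFAULT_K,
) -> DistanceMatrix:
    """All-against-all normalized LMS distances, entry order = input order."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in distance matrix input")
    n = len(records)
    indices = [fragment_index(r, k) for r in records]
    selfs = [diagonal_self_score(r, m) for r in records]
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        res_i = records[i].residues
        for j in range(i + 1, n):
            res_j = records[j].residues
            denom = selfs[i] + selfs[j]
            if denom <= 0:
                d = 1.0
            else:
                pos_i, pos_j = _coverage(indices[i], indices[j], k)
                num = sum(m.diagonal(res_i[p]) for p in pos_i) + sum(
                    m.diagonal(res_j[p]) for p in pos_j
                )
                d = min(1.0, max(0.0, 1.0 - num / denom))
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=ids, values=vals)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: a header of ids, then ``id TAB d1 TAB d2 ...``
    with six decimal places."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(dm.ids) + "\n")
        for i, pid in enumerate(dm.ids):
            row = "\t".join(f"{x:.6f}" for x in dm.values[i])
            fh.write(f"{pid}\t{row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a matrix written by :func:`write_distance_matrix`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        ids = tuple(header.split("\t"))
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in fields[1:]])
    return DistanceMatrix(ids=ids, values=np.array(rows))
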