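"""Reading and writing of protein sequence sets and domain-architecture tables.

The unit of analysis is a :class:`ProteinRecord` — an identifier plus an
amino-acid string over the 20 standard residues and ``X`` (unknown).  Domain
architectures are ordered N→C lists of domain identifiers supplied by the
user as a plain tab-delimited file; they are optional metadata and are never
inferred from the sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet accepted after normalization.
ALPHABET = frozenset(STANDARD_RESIDUES + "X")

# Ambiguity / nonstandard codes folded into X on read: the scoring matrix
# contract only defines a diagonal for the 20 standard residues plus X.
_NONSTANDARD_TO_X = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a unique identifier and its residue string.

    Residues are uppercase, over :data:`ALPHABET`; the identifier contains
    no tab or newline (it must survive round-trips through the TSV files).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if "\t" in self.id or "\n" in self.id:
            raise ValueError(f"protein id {self.id!r} contains tab/newline")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            ch = sorted(bad)[0]
            raise ValueError(
                f"record {self.id!r}: invalid residue character {ch!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered (N-terminal → C-terminal) list of domain identifiers.

    Duplicates are legal and meaningful: copy-number differences are what
    the duplication-similarity index measures.
    """

    protein_id: str
    domains: tuple[str, ...]


def _normalize_residues(record_id: str, raw: str) -> str:
    seq = "".join(raw.split()).upper().replace("*", "")
    mapped = []
    n_nonstandard = 0
    for ch in seq:
        if ch in _NONSTANDARD_TO_X:
            n_nonstandard += 1
            ch = _NONSTANDARD_TO_X[ch]
        mapped.append(ch)
    if n_nonstandard:
        logger.warning(
            "record %r: %d nonstandard residue(s) (B/Z/U/O/J) mapped to X",
            record_id, n_nonstandard,
        )
    return "".join(mapped)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    The id is the header token before the first whitespace (so it matches
    the keys of the architecture table); lowercase letters are uppercased,
    ``*`` stop characters and whitespace are stripped, and B/Z/U/O/J fold
    into ``X``.  Raises ``ValueError`` on an empty file, a duplicate id, or
    a character outside the 20+X alphabet.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        residues = _normalize_residues(rid, str(rec.seq))
        records.append(ProteinRecord(id=rid, residues=residues))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-line FASTA (60-character wrap)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_architectures(path: str | Path) -> dict[str, DomainArchitecture]:
    """Parse the tab-delimited architecture file.

    Each non-empty line is ``protein_id TAB domain1 TAB domain2 ...``; a
    line with only an id yields an architecture with an empty domain list
    (a protein with no assigned domains is legal).  Proteins absent from
    the file are simply absent from the mapping.
    """
    path = Path(path)
    archs: dict[str, DomainArchitecture] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            pid = fields[0].strip()
            if not pid:
                raise ValueError(f"{path}:{lineno}: missing protein id")
            if pid in archs:
                raise ValueError(
                    f"{path}:{lineno}: duplicate architecture entry for {pid!r}"
                )
            domains = tuple(f.strip() for f in fields[1:] if f.strip())
            archs[pid] = DomainArchitecture(protein_id=pid, domains=domains)
    return archs


def write_architectures(
    archs: Mapping[str, DomainArchitecture], path: str | Path
) -> None:
    """Write architectures as the same TSV format :func:`read_architectures` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in archs:
            fh.write("\t".join([pid, *archs[pid].domains]) + "\n")


def write_cluster_assignments(
    assignments: Mapping[str, int], path: str | Path
) -> None:
    """Write ``protein_id TAB cluster_index`` lines, sorted by cluster then id.

    Cluster indices must be positive integers (numbering starts at 1).
    """
    for pid, idx in assignments.items():
        if not isinstance(idx, int) or isinstance(idx, bool) or idx < 1:
            raise ValueError(
                f"cluster index for {pid!r} must be a positive integer, got {idx!r}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        for pid, idx in sorted(assignments.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{pid}\t{idx}\n")


def read_cluster_assignments(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``protein_id TAB cluster_index`` file."""
    path = Path(path)
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                pid, idx = line.split("\t")
                out[pid] = int(idx)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
    return out
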