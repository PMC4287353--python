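"""Synthetic multi-domain protein families with known ground truth.

The generator emulates the regime where alignment-based comparison breaks
down: proteins built by concatenating reusable domain blocks, diverging by
point substitutions, with some members undergoing domain-order shuffling or
circular permutation of their domain list.  Each domain type gets one random
master sequence; each family is an ordered architecture over domain types;
each member is its family's concatenated masters with i.i.d. substitutions.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import (
    STANDARD_RESIDUES,
    DomainArchitecture,
    ProteinRecord,
    write_architectures,
    write_fasta,
)

__all__ = ["SynthConfig", "default_config", "generate_dataset", "save_dataset"]


def _default_architectures(n_families: int, n_domain_types: int) -> tuple[tuple[str, ...], ...]:
    # Two private domain types per family plus one shared (promiscuous) type
    # appended C-terminally — the multi-domain regime where content separates
    # families but one domain recurs everywhere.
    if n_domain_types < 2 * n_families + 1:
        raise ValueError(
            f"default architectures need {2 * n_families + 1} domain types, "
            f"got {n_domain_types}"
        )
    shared = f"D{n_domain_types}"
    archs = []
    for f in range(n_families):
        archs.append((f"D{2 * f + 1}", f"D{2 * f + 2}", shared))
    return tuple(archs)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset.

    ``architectures`` maps one ordered domain-id list to each family; when
    ``None`` a default layout with one shared domain type is built.  Rates
    and fractions are per-residue / per-member probabilities in [0, 1].
    """

    n_families: int = 3
    members_per_family: int = 8
    n_domain_types: int = 7
    domain_length_range: tuple[int, int] = (30, 60)
    architectures: tuple[tuple[str, ...], ...] | None = None
    substitution_rate: float = 0.05
    shuffle_fraction: float = 0.25
    circular_permute_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.domain_length_range
        if lo < 5 or hi < lo:
            raise ValueError(
                f"domain lengths must satisfy 5 <= min <= max, got {self.domain_length_range}"
            )
        for name, val in (
            ("substitution_rate", self.substitution_rate),
            ("shuffle_fraction", self.shuffle_fraction),
            ("circular_permute_fraction", self.circular_permute_fraction),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member per family")
        if self.architectures is not None and len(self.architectures) != self.n_families:
            raise ValueError(
                f"{len(self.architectures)} architectures for {self.n_families} families"
            )

    def resolved_architectures(self) -> tuple[tuple[str, ...], ...]:
        if self.architectures is None:
            return _default_architectures(self.n_families, self.n_domain_types)
        known = {f"D{i + 1}" for i in range(self.n_domain_types)}
        for arch in self.architectures:
            unknown = set(arch) - known
            if unknown:
                raise ValueError(
                    f"architecture {arch} references unknown domain type(s) {sorted(unknown)}"
                )
        return tuple(tuple(a) for a in self.architectures)


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The study conditions used throughout the test-bed: 3 families × 8
    members, 5% substitutions, a quarter of members domain-shuffled."""
    return replace(SynthConfig(seed=seed), **overrides)


_RESIDUE_ARRAY = np.frombuffer(STANDARD_RESIDUES.encode(), dtype="S1")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute each position with prob ``rate``, replacement drawn
    uniformly from the 19 other standard residues."""
    if rate == 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    idx = np.nonzero(mask)[0]
    for i in idx:
        choices = _RESIDUE_ARRAY[_RESIDUE_ARRAY != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[list[ProteinRecord], dict[str, DomainArchitecture], dict[str, int]]:
    """Build (records, architectures, truth) for one configuration.

    ``truth`` maps each protein id to its 1-based family index.  A
    ``shuffle_fraction`` of each family's members receive a random
    permutation of their domain order and, among the remaining members, a
    ``circular_permute_fraction`` receive a circular rotation; architecture
    metadata follows the rearranged order.
    """
    rng = np.random.default_rng(cfg.seed)
    archs_by_family = cfg.resolved_architectures()
    lo, hi = cfg.domain_length_range

    masters: dict[str, np.ndarray] = {}
    for i in range(cfg.n_domain_types):
        length = int(rng.integers(lo, hi + 1))
        masters[f"D{i + 1}"] = _RESIDUE_ARRAY[rng.integers(len(_RESIDUE_ARRAY), size=length)]

    records: list[ProteinRecord] = []
    archs: dict[str, DomainArchitecture] = {}
    truth: dict[str, int] = {}
    m = cfg.members_per_family
    for f, family_arch in enumerate(archs_by_family, start=1):
        n_shuffle = int(round(cfg.shuffle_fraction * m))
        shuffled = set(rng.choice(m, size=n_shuffle, replace=False).tolist())
        rest = [i for i in range(m) if i not in shuffled]
        n_cp = int(round(cfg.circular_permute_fraction * m))
        permuted = set(
            np.array(rest)[rng.choice(len(rest), size=min(n_cp, len(rest)), replace=False)].tolist()
        ) if rest and n_cp else set()
        for i in range(m):
            order = list(family_arch)
            if i in shuffled and len(order) > 1:
                order = [order[j] for j in rng.permutation(len(order))]
            elif i in permuted and len(order) > 1:
                shift = int(rng.integers(1, len(order)))
                order = order[shift:] + order[:shift]
            seq = np.concatenate([masters[d] for d in order])
            seq = _mutate(seq, cfg.substitution_rate, rng)
            pid = f"fam{f}_m{i:02d}"
            records.append(ProteinRecord(id=pid, residues=seq.tobytes().decode()))
            archs[pid] = DomainArchitecture(protein_id=pid, domains=tuple(order))
            truth[pid] = f
    return records, archs, truth


def save_dataset(
    records: Sequence[ProteinRecord],
    archs: Mapping[str, DomainArchitecture],
    truth: Mapping[str, int],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + architecture TSV + truth-labels TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "architectures": outdir / "architectures.tsv",
        "truth": outdir / "truth_labels.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_architectures(archs, paths["architectures"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for pid, fam in truth.items():
            fh.write(f"{pid}\t{fam}\n")
    return paths
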