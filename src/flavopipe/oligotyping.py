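"""Oligotyping: positional entropy profiling of reads within one OTU.

Reads pre-aligned to the OTU consensus (gapped, equal length) are scanned
column by column for Shannon entropy over the 5-symbol alphabet {A,C,G,T,-}.
Sequencing errors scatter as low-entropy "white noise" along the alignment,
while a genuine sub-OTU polymorphism produces a sharp high-entropy site;
reads are then partitioned into oligotypes by their alleles at the selected
high-entropy positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ALPHABET = ("A", "C", "G", "T", "-")


@dataclass
class AlignmentColumnProfile:
    """Symbol counts and Shannon entropy (bits) of one alignment column;
    ``position`` is 1-based along the consensus."""

    position: int
    base_counts: dict[str, int]
    entropy: float


@dataclass
class OligotypeTable:
    """Oligotype (concatenated alleles at the selected positions) counts
    and relative frequencies over the reads used."""

    selected_positions: list[int]
    counts: dict[str, int]
    frequencies: dict[str, float] = field(init=False)
    n_reads: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_reads = sum(self.counts.values())
        self.frequencies = {k: v / self.n_reads for k, v in self.counts.items()}


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def column_entropy(aligned_reads: Sequence[str]) -> list[AlignmentColumnProfile]:
    """Per-column symbol counts and entropy for an equal-length alignment.

    Symbols outside {A,C,G,T,-} (e.g. ambiguity codes) are excluded from
    the counts.
    """
    if len(aligned_reads) == 0:
        raise ValueError("need at least one aligned read")
    lengths = {len(r) for r in aligned_reads}
    if len(lengths) != 1:
        raise ValueError("aligned reads must all have the same length")
    matrix = np.array([list(r.upper()) for r in aligned_reads])
    profiles = []
    for col in range(matrix.shape[1]):
        column = matrix[:, col]
        counts = {sym: int((column == sym).sum()) for sym in ALPHABET}
        profiles.append(
            AlignmentColumnProfile(
                position=col + 1,
                base_counts=counts,
                entropy=_entropy_bits(np.array(list(counts.values()))),
            )
        )
    return profiles


def select_entropy_sites(
    profiles: Sequence[AlignmentColumnProfile],
    cutoff: float = 0.2,
    max_sites: Optional[int] = None,
) -> list[int]:
    """Positions with entropy >= cutoff (default 0.2 bits, the tool
    authors' recommended threshold), ranked by entropy descending with
    ties broken by position, truncated to ``max_sites``."""
    hits = [p for p in profiles if p.entropy >= cutoff]
    hits.sort(key=lambda p: (-p.entropy, p.position))
    positions = [p.position for p in hits]
    if max_sites is not None:
        positions = positions[:max_sites]
    return positions


def assign_oligotypes(
    aligned_reads: Sequence[str], positions: Sequence[int]
) -> OligotypeTable:
    """Map each read to its allele string at the selected 1-based positions
    and tabulate oligotype counts/frequencies. With no positions selected
    every read collapses to the empty oligotype."""
    if len(aligned_reads) == 0:
        raise ValueError("need at least one aligned read")
    length = len(aligned_reads[0])
    for pos in positions:
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside alignment length {length}")
    counts: dict[str, int] = {}
    for read in aligned_reads:
        allele = "".join(read[pos - 1].upper() for pos in positions)
        counts[allele] = counts.get(allele, 0) + 1
    return OligotypeTable(selected_positions=list(positions), counts=counts)
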