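"""Coding-gene structure and deterministic coordinate/phase computations.

A gene is represented by the ordered CDS lengths of its coding exons (the
coding part only, in transcription direction).  All downstream analyses live
in CDS nucleotide coordinates, 1-based inclusive, so that codon arithmetic
stays literal: residue ``i`` occupies CDS nucleotides ``3i-2 .. 3i``.

An *internal junction* is the position between CDS nucleotides ``k`` and
``k+1`` where an intron falls, i.e. the 3' end of every exon except the last.
The *phase* of a junction is ``k mod 3``: 0 when the intron falls between
codons, 1 when it falls after the first nucleotide of a codon, 2 after the
second.  An exon whose 5' and 3' phases are equal is *symmetric* — the
classical compatibility signature for exon shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "IncompleteCdsError",
    "GenomicInterval",
    "GeneModel",
    "ExonPhasePair",
    "CodonSpan",
    "BoundaryPhaseEvent",
    "compute_phases",
    "residue_to_exons",
    "boundary_phase_of_site_codon",
    "codon_span",
]

SIDE_5PRIME = "5prime"
SIDE_3PRIME = "3prime"
SIDE_SPLIT = "split"


class IncompleteCdsError(ValueError):
    """Raised when a CDS length is not a multiple of 3.

    Such gene models are flagged as incomplete and excluded from every
    analysis rather than silently truncated.
    """


@dataclass(frozen=True)
class GenomicInterval:
    """One exon's genomic CDS interval, 1-based inclusive, used only for I/O."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """Ordered coding exons of one gene.

    Parameters
    ----------
    gene_id : str
        Stable identifier.
    exon_cds_lengths : sequence of int
        CDS length (nt) of each exon, 5'→3' in transcription direction;
        every length >= 1.
    species : str
        Pass-through label; carried into reports, never interpreted.
    genomic_intervals : sequence of GenomicInterval, optional
        One interval per exon, in transcription direction.  Only used to
        round-trip GTF/BED12; all analysis runs on CDS coordinates.
    """

    gene_id: str
    exon_cds_lengths: tuple
    species: str = ""
    genomic_intervals: Optional[tuple] = None

    def __post_init__(self) -> None:
        lengths = tuple(int(x) for x in self.exon_cds_lengths)
        if len(lengths) == 0:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        if any(l < 1 for l in lengths):
            raise ValueError(f"{self.gene_id}: exon CDS lengths must be >= 1")
        object.__setattr__(self, "exon_cds_lengths", lengths)
        if self.genomic_intervals is not None:
            gi = tuple(self.genomic_intervals)
            if len(gi) != len(lengths):
                raise ValueError(
                    f"{self.gene_id}: {len(gi)} genomic intervals for "
                    f"{len(lengths)} exons"
                )
            for iv, length in zip(gi, lengths):
                if iv.length != length:
                    raise ValueError(
                        f"{self.gene_id}: interval length {iv.length} != CDS "
                        f"length {length}"
                    )
            object.__setattr__(self, "genomic_intervals", gi)

    @cached_property
    def cumulative_lengths(self) -> np.ndarray:
        """CDS coordinate of the last nucleotide of each exon (1-based)."""
        return np.cumsum(np.asarray(self.exon_cds_lengths, dtype=np.int64))

    @property
    def L(self) -> int:
        """Total CDS length in nucleotides."""
        return int(self.cumulative_lengths[-1])

    @property
    def n_exons(self) -> int:
        return len(self.exon_cds_lengths)

    @property
    def is_complete(self) -> bool:
        return self.L % 3 == 0

    @property
    def n_residues(self) -> int:
        """Protein length; requires a complete CDS."""
        self.require_complete()
        return self.L // 3

    @cached_property
    def internal_junctions(self) -> tuple:
        """CDS slot positions k of all internal exon junctions (1 <= k <= L-1)."""
        return tuple(int(k) for k in self.cumulative_lengths[:-1])

    def require_complete(self) -> None:
        if self.L % 3 != 0:
            raise IncompleteCdsError(
                f"{self.gene_id}: CDS length {self.L} is not a multiple of 3; "
                "gene flagged incomplete and excluded"
            )


@dataclass(frozen=True)
class ExonPhasePair:
    """5' and 3' phases of one exon; ``symmetric`` iff the two are equal."""

    exon_index: int
    phase5: int
    phase3: int

    @property
    def symmetric(self) -> bool:
        return self.phase5 == self.phase3


@dataclass(frozen=True)
class CodonSpan:
    """CDS nucleotide span of one residue's codon (both ends inclusive)."""

    residue_index: int

    @property
    def nt_start(self) -> int:
        return 3 * self.residue_index - 2

    @property
    def nt_end(self) -> int:
        return 3 * self.residue_index


@dataclass(frozen=True)
class BoundaryPhaseEvent:
    """One internal junction adjacent to or inside a residue's codon.

    ``side`` is ``5prime``/``3prime`` for a phase-0 junction flanking the
    codon, ``split`` for a phase-1/2 junction that breaks it.
    """

    junction: int
    phase: int
    side: str


def codon_span(gene: GeneModel, residue_index: int) -> CodonSpan:
    """Return the CDS codon span of ``residue_index`` after range-checking."""
    n = gene.n_residues
    if not (1 <= residue_index <= n):
        raise ValueError(
            f"{gene.gene_id}: residue {residue_index} outside protein 1..{n}"
        )
    return CodonSpan(residue_index)


def compute_phases(gene: GeneModel) -> list:
    """Compute the 5'/3' phase of every exon.

    The 3' phase of exon ``i`` is the cumulative CDS length through exon
    ``i`` modulo 3; the 5' phase of the first exon is 0 and otherwise equals
    the previous exon's 3' phase.  The last exon of a complete CDS always
    closes in phase 0.
    """
    gene.require_complete()
    phase3 = gene.cumulative_lengths % 3
    pairs = []
    prev = 0
    for i, p3 in enumerate(phase3):
        pairs.append(ExonPhasePair(exon_index=i, phase5=prev, phase3=int(p3)))
        prev = int(p3)
    return pairs


def residue_to_exons(gene: GeneModel, residue_index: int) -> tuple:
    """Indices (0-based, ascending) of all exons intersecting the residue's codon.

    A codon spans at most one junction when every exon is >= 3 nt, so the
    result usually has one or two elements; it is never empty.
    """
    span = codon_span(gene, residue_index)
    cum = gene.cumulative_lengths
    first = int(np.searchsorted(cum, span.nt_start, side="left"))
    last = int(np.searchsorted(cum, span.nt_end, side="left"))
    return tuple(range(first, last + 1))


def boundary_phase_of_site_codon(gene: GeneModel, residue_index: int) -> list:
    """Internal junctions that break or flank the residue's codon, with phases.

    For residue ``i`` the relevant junction slots are ``3i-3`` (phase 0 at
    the codon's 5' flank), ``3i-2`` (phase 1, codon split), ``3i-1`` (phase
    2, codon split) and ``3i`` (phase 0 at the 3' flank).  An empty list
    means the codon sits strictly inside one exon, away from any junction.
    """
    span = codon_span(gene, residue_index)
    junctions = set(gene.internal_junctions)
    i = residue_index
    events = []
    for k in (3 * i - 3, 3 * i - 2, 3 * i - 1, 3 * i):
        if k < 1 or k > gene.L - 1 or k not in junctions:
            continue
        if k == 3 * i - 3:
            side = SIDE_5PRIME
        elif k == 3 * i:
            side = SIDE_3PRIME
        else:
            side = SIDE_SPLIT
        events.append(BoundaryPhaseEvent(junction=k, phase=k % 3, side=side))
    return events
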