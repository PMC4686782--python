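"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's arithmetic: they walk the CDS
nucleotide by nucleotide, so the closed-form phase and mapping code is
checked against literal enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from exonproj.gene_model import GeneModel


def brute_force_phases(lengths):
    """(phase5, phase3) per exon by filling codons one nucleotide at a time."""
    codon_fill = 0
    out = []
    for length in lengths:
        p5 = codon_fill
        for _ in range(length):
            codon_fill += 1
            if codon_fill == 3:
                codon_fill = 0
        out.append((p5, codon_fill))
    return out


def exon_of_nucleotide(lengths):
    """0-based exon index of every CDS nucleotide (list of length L)."""
    owner = []
    for e, length in enumerate(lengths):
        owner.extend([e] * length)
    return owner


def brute_force_residue_exons(lengths, residue):
    """Exons touched by residue's codon, via the per-nucleotide owner array."""
    owner = exon_of_nucleotide(lengths)
    span = owner[3 * residue - 3: 3 * residue]
    return tuple(sorted(set(span)))


def brute_force_borders_in_area(lengths, first, last):
    """Internal junctions inside the area's CDS slot range, by enumeration."""
    cum = np.cumsum(lengths)
    junctions = cum[:-1]
    a, b = 3 * first - 2, 3 * last
    return int(((junctions >= a) & (junctions <= b - 1)).sum())


def brute_force_ec_labels(lengths, residue_sets):
    """Set of EC exon indices by scanning every site nucleotide."""
    owner = exon_of_nucleotide(lengths)
    ec = set()
    for residues in residue_sets:
        for r in residues:
            ec.update(owner[3 * r - 3: 3 * r])
    return ec


def random_gene(rng, gene_id="g", min_exons=1, max_exons=12,
                min_len=1, max_len=300):
    """Random complete gene model (last exon padded to a full codon)."""
    n = int(rng.integers(min_exons, max_exons + 1))
    lengths = rng.integers(min_len, max_len + 1, size=n).astype(int)
    pad = (3 - int(lengths.sum()) % 3) % 3
    lengths[-1] += pad
    return GeneModel(gene_id=gene_id, exon_cds_lengths=tuple(int(l) for l in lengths))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_exon_gene():
    return GeneModel(gene_id="g45", exon_cds_lengths=(4, 5))
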