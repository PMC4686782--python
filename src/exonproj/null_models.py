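"""Resampling null models.

Two nulls drive the analyses:

* **Randomized exon boundaries** — for a gene of CDS length ``L`` with ``m``
  internal junctions, each replicate redraws the ``m`` junction positions
  uniformly without replacement from the ``L-1`` junction slots.  Counting
  resampled junctions inside a site area gives the expected discontinuity
  under structure-blind boundary placement; the replicate mean converges to
  the hypergeometric value ``m * slots / (L - 1)``.

* **Site-position permutation** — each replicate redraws a site's residue
  positions uniformly without replacement over the protein (or an eligible
  subset), giving the boundary-phase composition expected when sites carry
  no positional information.

Sampling is performed in CDS coordinates: the counted statistics live in
CDS space, so intron lengths are irrelevant to either null.  All draws are
reproducible: one top-level seed, with per-gene child seeds derived
deterministically from ``(seed, gene_id)`` so serial and per-gene runs agree.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .gene_model import GeneModel, boundary_phase_of_site_codon, residue_to_exons
from .site_projection import SiteAnnotation, SiteArea

__all__ = [
    "NullDistribution",
    "PhasePermutationResult",
    "resample_boundaries",
    "expected_borders_in_area",
    "closed_form_expected_borders",
    "permute_site_positions",
    "expected_phase_fractions",
    "child_rng",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullDistribution:
    """One resampled statistic: one value per replicate, plus provenance."""

    statistic_name: str
    replicate_values: tuple
    n_replicates: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        vals = tuple(self.replicate_values)
        if len(vals) != self.n_replicates:
            raise ValueError(
                f"{self.statistic_name}: {len(vals)} values for "
                f"{self.n_replicates} replicates"
            )
        object.__setattr__(self, "replicate_values", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))


@dataclass(frozen=True)
class PhasePermutationResult:
    """Permutation-expected boundary-phase composition of site codons.

    ``fractions`` maps phase (0/1/2) to a NullDistribution of per-replicate
    phase fractions; ``mean_counts`` is the mean event count per phase over
    replicates; ``n_dropped`` counts replicates with zero events (excluded
    from the fractions).
    """

    fractions: dict
    mean_counts: tuple
    n_replicates: int
    n_dropped: int
    seed: int


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic child generator for (seed, label, ...).

    Labels are hashed with CRC-32 so the stream depends only on the seed and
    the identifiers, not on iteration order.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(lbl.encode("utf-8")) for lbl in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _sample_without_replacement(
    rng: np.random.Generator, n_items: int, k: int, n_replicates: int
) -> np.ndarray:
    """(n_replicates, k) array of distinct ints in [0, n_items) per row.

    Uses rejection sampling when k is small relative to n_items (duplicates
    are then rare), falling back to full per-row permutation otherwise.
    Both paths are deterministic functions of the generator state.
    """
    if k > n_items:
        raise ValueError(f"cannot draw {k} distinct items from {n_items}")
    if k == 0:
        return np.empty((n_replicates, 0), dtype=np.int64)
    if 3 * k > n_items:
        tiled = np.tile(np.arange(n_items, dtype=np.int64), (n_replicates, 1))
        return rng.permuted(tiled, axis=1)[:, :k]
    draws = rng.integers(0, n_items, size=(n_replicates, k), dtype=np.int64)
    while True:
        s = np.sort(draws, axis=1)
        bad = np.nonzero((s[:, 1:] == s[:, :-1]).any(axis=1))[0]
        if bad.size == 0:
            return draws
        draws[bad] = rng.integers(0, n_items, size=(bad.size, k), dtype=np.int64)


def resample_boundaries(
    L: int,
    m: int,
    n_replicates: int = 10,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Replicates of ``m`` junction positions drawn uniformly from {1..L-1}.

    Returns a list of sorted int arrays, one per replicate.
    """
    if not (0 <= m <= L - 1):
        raise ValueError(f"junction count {m} not in 0..{L - 1}")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = _sample_without_replacement(rng, L - 1, m, n_replicates) + 1
    return [np.sort(row) for row in draws]


def closed_form_expected_borders(area: SiteArea, L: int, m: int) -> float:
    """Hypergeometric mean border count: m * slots_in_area / (L - 1)."""
    return m * area.n_border_slots / (L - 1)


def expected_borders_in_area(
    area: SiteArea,
    L: int,
    m: int,
    n_replicates: int = 10,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NullDistribution:
    """Null distribution of border counts inside one site area.

    Each replicate redraws the gene's ``m`` junctions uniformly and counts
    how many fall in the area's slot range ``[nt_start, nt_end - 1]``.
    """
    a, b = area.nt_span
    if b > L:
        raise ValueError(f"site area nt span {a}..{b} exceeds CDS length {L}")
    if not (0 <= m <= L - 1):
        raise ValueError(f"junction count {m} not in 0..{L - 1}")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = _sample_without_replacement(rng, L - 1, m, n_replicates) + 1
    counts = ((draws >= a) & (draws <= b - 1)).sum(axis=1)
    return NullDistribution(
        statistic_name="borders_in_area",
        replicate_values=tuple(int(c) for c in counts),
        n_replicates=n_replicates,
        seed=seed,
    )


def permute_site_positions(
    protein_length: int,
    n_residues: int,
    n_replicates: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    eligible_positions: Optional[Iterable[int]] = None,
) -> list:
    """Replicates of ``n_residues`` positions drawn uniformly without replacement.

    By default every position 1..protein_length is eligible; an explicit
    eligible set restricts the draw (e.g. to residues outside terminal
    exons).  Returns a list of sorted int arrays.
    """
    if eligible_positions is None:
        eligible = np.arange(1, protein_length + 1, dtype=np.int64)
    else:
        eligible = np.asarray(sorted(set(int(p) for p in eligible_positions)),
                              dtype=np.int64)
        if eligible.size and (eligible[0] < 1 or eligible[-1] > protein_length):
            raise ValueError("eligible positions outside 1..protein_length")
    if n_residues > eligible.size:
        raise ValueError(
            f"cannot place {n_residues} residues on {eligible.size} eligible positions"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = _sample_without_replacement(rng, eligible.size, n_residues, n_replicates)
    return [np.sort(eligible[row]) for row in idx]


def _residue_phase_table(gene: GeneModel) -> np.ndarray:
    """(n_residues, 3) table: boundary-phase event counts per residue.

    Row r-1 holds, for residue r, how many internal junctions associate with
    its codon in each phase.  Each phase-0 junction contributes one event to
    each flanking residue; a phase-1/2 junction contributes one event to the
    residue whose codon it splits.
    """
    n = gene.n_residues
    table = np.zeros((n, 3), dtype=np.int64)
    for k in gene.internal_junctions:
        phase = k % 3
        if phase == 0:
            i = k // 3
            table[i - 1, 0] += 1       # 3' flank of residue i
            if i + 1 <= n:
                table[i, 0] += 1       # 5' flank of residue i+1
        elif phase == 1:
            table[(k + 2) // 3 - 1, 1] += 1
        else:
            table[(k + 1) // 3 - 1, 2] += 1
    return table


def _eligible_interior_positions(gene: GeneModel) -> np.ndarray:
    """Residues whose codon does not touch the first or last exon."""
    last = gene.n_exons - 1
    keep = [
        r for r in range(1, gene.n_residues + 1)
        if not ({0, last} & set(residue_to_exons(gene, r)))
    ]
    return np.asarray(keep, dtype=np.int64)


def expected_phase_fractions(
    sample: Sequence,
    n_replicates: int = 1000,
    seed: int = 0,
    exclude_terminal_exon_residues: bool = False,
) -> PhasePermutationResult:
    """Permutation-expected phase composition of boundary-associated site codons.

    ``sample`` is a sequence of ``(gene, sites)`` pairs.  For each replicate
    every site's residues are re-placed uniformly without replacement over
    the protein; the boundary-phase events of the permuted residues are
    pooled over the whole sample and converted to per-phase fractions.
    Replicates with zero events are dropped (logged).

    Per-gene substreams are derived from ``(seed, gene_id)``, so the result
    does not depend on the order in which genes are processed.
    """
    counts = np.zeros((n_replicates, 3), dtype=np.int64)
    n_junctions = 0
    for gene, sites in sample:
        gene.require_complete()
        n_junctions += len(gene.internal_junctions)
        if not sites:
            continue
        table = _residue_phase_table(gene)
        if exclude_terminal_exon_residues:
            eligible = _eligible_interior_positions(gene)
        else:
            eligible = np.arange(1, gene.n_residues + 1, dtype=np.int64)
        rng = child_rng(seed, gene.gene_id)
        for site in sites:
            k = site.n_residues
            if k > eligible.size:
                logger.warning(
                    "site %s: %d residues exceed %d eligible positions; skipped",
                    site.site_id, k, eligible.size,
                )
                continue
            idx = _sample_without_replacement(rng, eligible.size, k, n_replicates)
            counts += table[eligible[idx] - 1].sum(axis=1)
    if n_junctions == 0:
        raise ValueError("no junctions: sample contains no multi-exon gene")
    totals = counts.sum(axis=1)
    kept = totals > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("dropped %d replicates with zero boundary events", n_dropped)
    if not kept.any():
        raise ValueError("no boundary events in any replicate")
    frac = counts[kept] / totals[kept, None]
    fractions = {
        phase: NullDistribution(
            statistic_name=f"phase{phase}_fraction",
            replicate_values=tuple(float(v) for v in frac[:, phase]),
            n_replicates=int(kept.sum()),
            seed=seed,
        )
        for phase in (0, 1, 2)
    }
    return PhasePermutationResult(
        fractions=fractions,
        mean_counts=tuple(float(c) for c in counts.mean(axis=0)),
        n_replicates=n_replicates,
        n_dropped=n_dropped,
        seed=seed,
    )
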