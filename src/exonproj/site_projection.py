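"""Functional-site annotations, EC/ENC exon classification and site areas.

An exon is *EC* (site-coding) when it codes at least one residue of at least
one functional site, otherwise *ENC*.  A residue whose codon straddles a
junction makes both flanking exons EC.  The *site area* is the protein
segment from the first to the last residue of a site; the *discontinuity*
of a site is the number of internal exon junctions falling inside that
area's CDS span (equivalently, the number of exons spanning the area minus
one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .gene_model import (
    BoundaryPhaseEvent,
    GeneModel,
    boundary_phase_of_site_codon,
    compute_phases,
    residue_to_exons,
)

__all__ = [
    "SiteAnnotation",
    "SiteArea",
    "ExonRecord",
    "ProjectionResult",
    "classify_exons",
    "build_site_area",
    "observed_discontinuity",
    "filter_buffer_ligands",
    "pick_representatives",
]

logger = logging.getLogger(__name__)

LABEL_EC = "EC"
LABEL_ENC = "ENC"


@dataclass(frozen=True)
class SiteAnnotation:
    """One functional (ligand-binding) site on one protein.

    ``residues`` are 1-based positions in the protein sequence; they are
    sorted and de-duplicated on construction.  ``is_buffer_ligand`` marks
    ligands that typically enter a structure through crystallization or
    buffering rather than biology, so they can be excluded as a sensitivity
    analysis.
    """

    protein_id: str
    gene_id: str
    site_id: str
    ligand_id: str
    ligand_category: str
    residues: tuple
    is_buffer_ligand: bool = False

    def __post_init__(self) -> None:
        res = tuple(sorted({int(r) for r in self.residues}))
        if not res:
            raise ValueError(f"site {self.site_id}: empty residue list")
        if res[0] < 1:
            raise ValueError(f"site {self.site_id}: residues must be >= 1")
        object.__setattr__(self, "residues", res)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteArea:
    """Protein segment bounded by the first and last residue of a site."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not (1 <= self.first <= self.last):
            raise ValueError(f"bad site area {self.first}..{self.last}")

    @property
    def nt_span(self) -> tuple:
        """CDS nucleotide span (start, end), both inclusive."""
        return (3 * self.first - 2, 3 * self.last)

    @property
    def n_residues_spanned(self) -> int:
        return self.last - self.first + 1

    @property
    def n_border_slots(self) -> int:
        """Junction slots k with start <= k <= end-1 that the area can contain."""
        start, end = self.nt_span
        return end - start


@dataclass(frozen=True)
class ExonRecord:
    """One classified exon: phases, EC/ENC label and boundary flags."""

    gene_id: str
    exon_index: int
    cds_length: int
    phase5: int
    phase3: int
    label: str
    is_terminal: bool
    codes_site_residue_at_5prime: bool = False
    codes_site_residue_at_3prime: bool = False

    @property
    def symmetric(self) -> bool:
        return self.phase5 == self.phase3


@dataclass(frozen=True)
class ProjectionResult:
    """Observed projection of one site area onto the exon structure."""

    site_id: str
    gene_id: str
    n_internal_borders_in_area: int
    n_exons_spanning_area: int
    exon_indices: tuple
    boundary_phase_events: tuple  # (residue, phase, side) per event

    def __post_init__(self) -> None:
        if self.n_exons_spanning_area != self.n_internal_borders_in_area + 1:
            raise ValueError(
                f"{self.site_id}: {self.n_exons_spanning_area} exons vs "
                f"{self.n_internal_borders_in_area} internal borders"
            )


def _valid_sites(gene: GeneModel, sites: Iterable[SiteAnnotation]) -> list:
    """Sites referencing this gene whose residues all fit the protein."""
    n = gene.n_residues
    kept = []
    for site in sites:
        if site.gene_id != gene.gene_id:
            raise ValueError(
                f"site {site.site_id} references gene {site.gene_id}, "
                f"not {gene.gene_id}"
            )
        if site.residues[-1] > n:
            logger.warning(
                "site %s: residue %d beyond protein length %d; site skipped",
                site.site_id, site.residues[-1], n,
            )
            continue
        kept.append(site)
    return kept


def classify_exons(gene: GeneModel, sites: Sequence[SiteAnnotation]) -> list:
    """Label every exon of ``gene`` as EC or ENC against the given sites.

    EC exons intersect the codon span of at least one site residue (union
    over all valid sites).  The boundary flags record whether some site
    residue's codon covers the exon's first / last CDS nucleotide — the
    exons the phase analysis singles out at the 5' and 3' borders.
    """
    phases = compute_phases(gene)
    cum = gene.cumulative_lengths
    starts = np.concatenate(([1], cum[:-1] + 1))
    ec = set()
    flag5 = set()
    flag3 = set()
    for site in _valid_sites(gene, sites):
        for r in site.residues:
            exons = residue_to_exons(gene, r)
            ec.update(exons)
            a, b = 3 * r - 2, 3 * r
            for e in exons:
                if a <= starts[e] <= b:
                    flag5.add(e)
                if a <= cum[e] <= b:
                    flag3.add(e)
    last = gene.n_exons - 1
    return [
        ExonRecord(
            gene_id=gene.gene_id,
            exon_index=i,
            cds_length=gene.exon_cds_lengths[i],
            phase5=phases[i].phase5,
            phase3=phases[i].phase3,
            label=LABEL_EC if i in ec else LABEL_ENC,
            is_terminal=(i == 0 or i == last),
            codes_site_residue_at_5prime=i in flag5,
            codes_site_residue_at_3prime=i in flag3,
        )
        for i in range(gene.n_exons)
    ]


def build_site_area(site: SiteAnnotation) -> SiteArea:
    """Site area bounded by the first and last site residue."""
    return SiteArea(first=site.residues[0], last=site.residues[-1])


def observed_discontinuity(gene: GeneModel, site: SiteAnnotation) -> ProjectionResult:
    """Observed exon-border count and exon span of one site area.

    Counts internal junctions k with ``nt_start <= k <= nt_end - 1`` of the
    area's CDS span, and collects the boundary-phase events of every site
    residue's codon.
    """
    if not _valid_sites(gene, [site]):
        raise ValueError(f"site {site.site_id}: residues outside protein")
    area = build_site_area(site)
    a, b = area.nt_span
    borders = [k for k in gene.internal_junctions if a <= k <= b - 1]
    cum = gene.cumulative_lengths
    first_exon = int(np.searchsorted(cum, a, side="left"))
    last_exon = int(np.searchsorted(cum, b, side="left"))
    events = tuple(
        (r, ev.phase, ev.side)
        for r in site.residues
        for ev in boundary_phase_of_site_codon(gene, r)
    )
    return ProjectionResult(
        site_id=site.site_id,
        gene_id=gene.gene_id,
        n_internal_borders_in_area=len(borders),
        n_exons_spanning_area=last_exon - first_exon + 1,
        exon_indices=tuple(range(first_exon, last_exon + 1)),
        boundary_phase_events=events,
    )


def filter_buffer_ligands(
    sites: Sequence[SiteAnnotation],
    exclusion_categories: Iterable[str],
) -> list:
    """Drop sites whose ligand category is on the exclusion list.

    Category names on the list that never occur among the sites trigger a
    warning but are otherwise ignored.
    """
    excl = set(exclusion_categories)
    if not excl:
        return list(sites)
    present = {s.ligand_category for s in sites}
    for unknown in sorted(excl - present):
        logger.warning("exclusion category %r not present in the sample", unknown)
    kept = [s for s in sites if s.ligand_category not in excl]
    logger.info("buffer-ligand filter removed %d of %d sites",
                len(sites) - len(kept), len(sites))
    return kept


def pick_representatives(
    ids: Sequence[str],
    group_labels: Sequence[str],
    seed: int = 0,
) -> list:
    """Pick one id per group label, uniformly at random within each group.

    A lightweight stand-in for redundancy reduction when the caller already
    knows which entries are near-duplicates of each other.
    """
    if len(ids) != len(group_labels):
        raise ValueError("ids and group_labels must have equal length")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for i, g in zip(ids, group_labels):
        groups.setdefault(g, []).append(i)
    return [members[rng.integers(len(members))] for _, members in sorted(groups.items())]
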