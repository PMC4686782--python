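"""Readers and writers for gene structures (GTF/BED12) and site tables (TSV).

Coordinate conventions are converted at the boundary: GTF is 1-based
inclusive, BED12 is 0-based half-open; internally everything is the
1-based-inclusive CDS convention of :mod:`exonproj.gene_model`.  Minus-strand
genes are reordered into transcription direction at load time so all
downstream logic is strand-free.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import gffutils
import pandas as pd
import yaml

from .gene_model import GeneModel, GenomicInterval
from .site_projection import SiteAnnotation

__all__ = [
    "RunConfig",
    "read_gene_models",
    "write_gene_models_gtf",
    "write_gene_models_bed12",
    "read_sites",
    "write_sites",
    "read_protein_gene_map",
    "write_protein_gene_map",
]

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["protein_id", "gene_id", "site_id", "ligand_id",
                "ligand_category", "residues", "is_buffer_ligand"]


@dataclass
class RunConfig:
    """Validated run configuration, serialized into every output bundle."""

    genes_path: Optional[str] = None
    sites_path: Optional[str] = None
    out_dir: str = "exonproj_out"
    seed: int = 0
    boundary_replicates: int = 10
    permutations: int = 1000
    exclude_terminal_exons_everywhere: bool = False
    exclude_buffer_ligands: bool = False
    buffer_categories: tuple = ()
    bin_width: float = 3.0
    min_expected: float = 5.0
    exon_count_cap: int = 7
    stages: tuple = ("lengths", "discontinuity", "phases", "categories")

    def __post_init__(self) -> None:
        if self.boundary_replicates < 1 or self.permutations < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.buffer_categories = tuple(self.buffer_categories)
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["buffer_categories"] = list(self.buffer_categories)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# gene structures

def read_gene_models(path, fmt: Optional[str] = None,
                     on_multiple_isoforms: str = "longest") -> List[GeneModel]:
    """Load gene models from GTF or BED12.

    Transcripts whose CDS length is not a multiple of 3 are flagged,
    excluded and logged.  When a GTF gene carries several transcripts the
    longest CDS is taken by default (``on_multiple_isoforms="error"`` raises
    instead).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gtf": "gtf", "gff": "gtf", "bed": "bed12"}.get(
            suffix.lstrip("."), None)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "gtf":
        models = _read_gtf(path, on_multiple_isoforms)
    elif fmt == "bed12":
        models = _read_bed12(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    complete = []
    for gene in models:
        if gene.is_complete:
            complete.append(gene)
        else:
            logger.warning("%s: CDS length %d not a multiple of 3; excluded",
                           gene.gene_id, gene.L)
    return complete


def _read_gtf(path: Path, on_multiple_isoforms: str) -> List[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:",
        force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_tx: Dict[str, list] = {}
    tx_meta: Dict[str, dict] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        tx = feat.attributes.get("transcript_id", [None])[0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        if tx is None:
            raise ValueError(f"{path.name}: CDS feature without transcript_id "
                             f"at {feat.seqid}:{feat.start}")
        species = feat.attributes.get("species", [""])[0]
        per_tx.setdefault(tx, []).append(feat)
        tx_meta[tx] = {"gene_id": gene, "species": species}
    by_gene: Dict[str, list] = {}
    for tx, feats in per_tx.items():
        by_gene.setdefault(tx_meta[tx]["gene_id"], []).append(tx)
    models = []
    for gene_id in by_gene:
        txs = by_gene[gene_id]
        if len(txs) > 1:
            if on_multiple_isoforms == "error":
                raise ValueError(f"{gene_id}: multiple transcripts {sorted(txs)}")
            txs = [max(txs, key=lambda t: sum(
                f.end - f.start + 1 for f in per_tx[t]))]
        tx = txs[0]
        feats = sorted(per_tx[tx], key=lambda f: f.start)
        strand = feats[0].strand
        if strand not in ("+", "-"):
            raise ValueError(f"{gene_id}: missing strand")
        if strand == "-":
            feats = feats[::-1]
        intervals = tuple(
            GenomicInterval(f.seqid, f.start, f.end, strand) for f in feats)
        lengths = tuple(iv.length for iv in intervals)
        models.append(GeneModel(
            gene_id=gene_id, exon_cds_lengths=lengths,
            species=tx_meta[tx]["species"], genomic_intervals=intervals))
    models.sort(key=lambda g: g.gene_id)
    return models


def _require_intervals(gene: GeneModel) -> None:
    if gene.genomic_intervals is None:
        raise ValueError(f"{gene.gene_id}: no genomic intervals; cannot write")


def write_gene_models_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write CDS features in Ensembl-flavoured GTF, one transcript per gene."""
    lines = []
    for gene in genes:
        _require_intervals(gene)
        cum = 0
        rows = list(zip(gene.genomic_intervals, gene.exon_cds_lengths))
        frames = []
        for _, length in rows:
            frames.append((3 - cum % 3) % 3)
            cum += length
        # file order is genomic order; transcription order for '-' is reversed
        order = range(len(rows)) if rows[0][0].strand == "+" else \
            range(len(rows) - 1, -1, -1)
        for i in order:
            iv, _ = rows[i]
            attrs = (f'gene_id "{gene.gene_id}"; '
                     f'transcript_id "{gene.gene_id}.t1";')
            if gene.species:
                attrs += f' species "{gene.species}";'
            lines.append("\t".join([
                iv.chrom, "exonproj", "CDS", str(iv.start), str(iv.end),
                ".", iv.strand, str(frames[i]), attrs,
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    """Write one BED12 line per gene (0-based half-open; blocks = CDS exons)."""
    lines = []
    for gene in genes:
        _require_intervals(gene)
        ivs = sorted(gene.genomic_intervals, key=lambda iv: iv.start)
        chrom = ivs[0].chrom
        chrom_start = ivs[0].start - 1
        chrom_end = ivs[-1].end
        sizes = ",".join(str(iv.length) for iv in ivs)
        starts = ",".join(str(iv.start - 1 - chrom_start) for iv in ivs)
        lines.append("\t".join([
            chrom, str(chrom_start), str(chrom_end), gene.gene_id, "0",
            ivs[0].strand, str(chrom_start), str(chrom_end), "0",
            str(len(ivs)), sizes, starts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_bed12(path: Path) -> List[GeneModel]:
    names = ["chrom", "chromStart", "chromEnd", "name", "score", "strand",
             "thickStart", "thickEnd", "itemRgb", "blockCount",
             "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    models = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            if len(sizes) != int(row.blockCount) or len(sizes) != len(offsets):
                raise ValueError("block count mismatch")
            thick_lo, thick_hi = int(row.thickStart), int(row.thickEnd)
            intervals = []
            for size, off in zip(sizes, offsets):
                lo = int(row.chromStart) + off
                hi = lo + size
                lo, hi = max(lo, thick_lo), min(hi, thick_hi)
                if hi > lo:
                    intervals.append(GenomicInterval(
                        str(row.chrom), lo + 1, hi, str(row.strand)))
            if not intervals:
                raise ValueError("no coding blocks inside thick region")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: malformed BED12 line {line_no}: {exc}")
        if str(row.strand) == "-":
            intervals = intervals[::-1]
        models.append(GeneModel(
            gene_id=str(row.name),
            exon_cds_lengths=tuple(iv.length for iv in intervals),
            genomic_intervals=tuple(intervals)))
    models.sort(key=lambda g: g.gene_id)
    return models


# ---------------------------------------------------------------------------
# site tables

def write_sites(sites: Sequence[SiteAnnotation], path) -> None:
    rows = [{
        "protein_id": s.protein_id,
        "gene_id": s.gene_id,
        "site_id": s.site_id,
        "ligand_id": s.ligand_id,
        "ligand_category": s.ligand_category,
        "residues": ",".join(str(r) for r in s.residues),
        "is_buffer_ligand": int(s.is_buffer_ligand),
    } for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites(path, genes: Optional[Sequence[GeneModel]] = None) -> List[SiteAnnotation]:
    """Parse a site TSV; rows referencing unknown genes or with unparsable
    residue lists are rejected and logged.  Duplicate residues collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    known = None if genes is None else {g.gene_id: g for g in genes}
    sites = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        gene_id = str(row.gene_id)
        if known is not None and gene_id not in known:
            logger.warning("%s line %d: unknown gene_id %r; row rejected",
                           Path(path).name, line_no, gene_id)
            continue
        try:
            residues = tuple(int(x) for x in str(row.residues).split(","))
        except ValueError:
            logger.warning("%s line %d: unparsable residues %r; row rejected",
                           Path(path).name, line_no, row.residues)
            continue
        buf = getattr(row, "is_buffer_ligand", "0")
        is_buffer = str(buf).strip().lower() in ("1", "true", "yes")
        site = SiteAnnotation(
            protein_id=str(row.protein_id), gene_id=gene_id,
            site_id=str(row.site_id), ligand_id=str(row.ligand_id),
            ligand_category=str(row.ligand_category), residues=residues,
            is_buffer_ligand=is_buffer)
        if known is not None and site.residues[-1] > known[gene_id].n_residues:
            logger.warning("%s line %d: residue %d beyond protein length %d; "
                           "row rejected", Path(path).name, line_no,
                           site.residues[-1], known[gene_id].n_residues)
            continue
        sites.append(site)
    return sites


def write_protein_gene_map(sites: Sequence[SiteAnnotation],
                           genes: Sequence[GeneModel], path) -> None:
    by_gene = {g.gene_id: g for g in genes}
    pairs = sorted({(s.protein_id, s.gene_id) for s in sites})
    rows = [{
        "protein_id": p, "gene_id": g,
        "species": by_gene[g].species if g in by_gene else "",
        "protein_length": by_gene[g].n_residues if g in by_gene else "",
    } for p, g in pairs]
    pd.DataFrame(rows, columns=["protein_id", "gene_id", "species",
                                "protein_length"]).to_csv(path, sep="\t",
                                                          index=False)


def read_protein_gene_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_id": str})
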