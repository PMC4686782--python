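"""End-to-end analysis stages and report assembly.

Four stages mirror the analyses: ``lengths`` (EC vs ENC exon-length
comparison), ``discontinuity`` (observed vs boundary-resampled exon counts
per site area), ``phases`` (junction-phase contingency tables, the site-codon
boundary-phase census against the permutation null, and a per-gene paired
Wilcoxon), and ``categories`` (ligand-category composition overall and among
symmetric phase-0 site-coding exons).  ``run_all`` executes them with one
shared seed and writes a TSV + JSON bundle whose bytes are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .gene_model import GeneModel, compute_phases
from .io import RunConfig
from .null_models import (
    PhasePermutationResult,
    child_rng,
    expected_borders_in_area,
    expected_phase_fractions,
)
from .site_projection import (
    LABEL_EC,
    LABEL_ENC,
    ExonRecord,
    SiteAnnotation,
    build_site_area,
    classify_exons,
    filter_buffer_ligands,
    observed_discontinuity,
)
from .stats_tests import (
    TestResult,
    chi2_binned,
    chi2_contingency,
    mann_whitney_u,
    wilcoxon_signed_rank,
)

__all__ = [
    "AnalysisReport",
    "stage_lengths",
    "stage_discontinuity",
    "stage_phases",
    "stage_ligand_categories",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """One stage's tables, test results and provenance metadata."""

    stage: str
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: List[TestResult] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return "error" not in self.metadata

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            rows.append({
                "test": t.statistic_name,
                "statistic": t.statistic_value,
                "df": t.df if t.df is not None else "",
                "p_value": t.p_value,
                "n1": t.n1 if t.n1 is not None else "",
                "n2": t.n2 if t.n2 is not None else "",
                "correction": t.correction,
                "extra": json.dumps(t.extra, sort_keys=True),
            })
        return pd.DataFrame(rows, columns=["test", "statistic", "df", "p_value",
                                           "n1", "n2", "correction", "extra"])

    def write(self, out_dir) -> list:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in sorted(self.tables.items()):
            p = out / f"{self.stage}_{name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            written.append(p)
        if self.tests:
            p = out / f"{self.stage}_tests.tsv"
            self.tests_frame().to_csv(p, sep="\t", index=False)
            written.append(p)
        meta = out / f"{self.stage}_metadata.json"
        meta.write_text(json.dumps(self.metadata, indent=1, sort_keys=True) + "\n")
        written.append(meta)
        return written


def _group_sites(genes: Sequence[GeneModel],
                 sites: Sequence[SiteAnnotation]) -> Dict[str, list]:
    known = {g.gene_id for g in genes}
    grouped: Dict[str, list] = {g: [] for g in known}
    dropped = 0
    for s in sites:
        if s.gene_id in known:
            grouped[s.gene_id].append(s)
        else:
            dropped += 1
    if dropped:
        logger.warning("%d sites reference unknown genes and were dropped", dropped)
    return grouped


def _classified(genes: Sequence[GeneModel],
                grouped: Dict[str, list]) -> List[ExonRecord]:
    records: List[ExonRecord] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        records.extend(classify_exons(gene, grouped[gene.gene_id]))
    return records


def _exon_frame(records: Sequence[ExonRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id,
        "exon_number": r.exon_index + 1,   # 1-based in reports
        "cds_length": r.cds_length,
        "phase5": r.phase5,
        "phase3": r.phase3,
        "symmetric": int(r.symmetric),
        "label": r.label,
        "is_terminal": int(r.is_terminal),
        "site_at_5prime": int(r.codes_site_residue_at_5prime),
        "site_at_3prime": int(r.codes_site_residue_at_3prime),
    } for r in records])


def _apply_filters(genes, sites, config: RunConfig):
    sites = list(sites)
    if config.exclude_buffer_ligands:
        if config.buffer_categories:
            sites = filter_buffer_ligands(sites, config.buffer_categories)
        else:
            sites = [s for s in sites if not s.is_buffer_ligand]
    return list(genes), sites


# ---------------------------------------------------------------------------
# lengths

def stage_lengths(genes: Sequence[GeneModel], sites: Sequence[SiteAnnotation],
                  config: Optional[RunConfig] = None) -> AnalysisReport:
    """EC vs ENC exon-length distributions with chi-square and Mann-Whitney.

    Terminal exons are included by default; set
    ``exclude_terminal_exons_everywhere`` to drop them here too.
    """
    config = config or RunConfig()
    genes, sites = _apply_filters(genes, sites, config)
    grouped = _group_sites(genes, sites)
    records = _classified(genes, grouped)
    if config.exclude_terminal_exons_everywhere:
        records = [r for r in records if not r.is_terminal]
    frame = _exon_frame(records)
    report = AnalysisReport(stage="lengths", metadata={
        "n_genes": len(genes), "n_sites": len(sites), "n_exons": len(records),
        "terminal_exons_excluded": config.exclude_terminal_exons_everywhere,
        "bin_width": config.bin_width, "min_expected": config.min_expected,
    })
    report.tables["exons"] = frame
    ec = [r.cds_length for r in records if r.label == LABEL_EC]
    enc = [r.cds_length for r in records if r.label == LABEL_ENC]
    if not ec or not enc:
        report.metadata["error"] = "no data: one of the EC/ENC classes is empty"
        return report
    summary = pd.DataFrame([
        {"class": LABEL_EC, "n": len(ec), "mean": float(np.mean(ec)),
         "median": float(np.median(ec)), "sd": float(np.std(ec, ddof=1))},
        {"class": LABEL_ENC, "n": len(enc), "mean": float(np.mean(enc)),
         "median": float(np.median(enc)), "sd": float(np.std(enc, ddof=1))},
    ])
    report.tables["summary"] = summary
    # histogram of both classes on a shared grid, for plotting downstream
    width = max(config.bin_width, 1.0) * 10
    lo = 0.0
    hi = float(max(max(ec), max(enc)))
    edges = np.arange(lo, hi + width, width)
    ce, _ = np.histogram(ec, bins=edges)
    cn, _ = np.histogram(enc, bins=edges)
    report.tables["length_histogram"] = pd.DataFrame({
        "bin_start_nt": edges[:-1].astype(int),
        "bin_end_nt": edges[1:].astype(int),
        "ec_count": ce,
        "enc_count": cn,
    })
    try:
        report.tests.append(chi2_binned(ec, enc, bin_width=config.bin_width,
                                        min_expected=config.min_expected))
    except ValueError as exc:
        report.metadata["chi2_binned_skipped"] = str(exc)
    report.tests.append(mann_whitney_u(ec, enc))
    return report


# ---------------------------------------------------------------------------
# discontinuity

def _capped(counts: Sequence[int], cap: int) -> np.ndarray:
    """Histogram of exon counts 1..cap, with >= cap pooled into the top bin."""
    arr = np.minimum(np.asarray(counts, dtype=np.int64), cap)
    return np.bincount(arr, minlength=cap + 1)[1:]


def stage_discontinuity(genes: Sequence[GeneModel],
                        sites: Sequence[SiteAnnotation],
                        config: Optional[RunConfig] = None) -> AnalysisReport:
    """Observed vs boundary-resampled exon counts over site areas.

    For every site on a multi-exon gene the observed number of exons
    spanning the site area is compared with counts from replicates that
    redraw the gene's junction positions uniformly (default 10 per gene).
    The two count distributions are compared by chi-square (counts capped at
    ``exon_count_cap``) and Mann-Whitney, and additionally by a paired sign
    test of each site's observed border count against one independent null
    draw (the first replicate).  The sign test respects the pairing of
    observed and resampled counts on the same site area, so it is exactly
    calibrated when junction positions are exchangeable with the null;
    the unpaired Mann-Whitney ignores that pairing and is reported for
    comparability with common practice.
    """
    config = config or RunConfig()
    genes, sites = _apply_filters(genes, sites, config)
    grouped = _group_sites(genes, sites)
    report = AnalysisReport(stage="discontinuity", metadata={
        "seed": config.seed,
        "boundary_replicates": config.boundary_replicates,
        "exon_count_cap": config.exon_count_cap,
        "n_genes": len(genes), "n_sites": len(sites),
    })
    rows = []
    observed: List[int] = []
    expected: List[int] = []
    wins = losses = ties = 0
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.n_exons < 2:
            continue
        rng = child_rng(config.seed, "discontinuity", gene.gene_id)
        for site in sorted(grouped[gene.gene_id], key=lambda s: s.site_id):
            try:
                proj = observed_discontinuity(gene, site)
            except ValueError as exc:
                logger.warning("%s", exc)
                continue
            area = build_site_area(site)
            null = expected_borders_in_area(
                area, gene.L, gene.n_exons - 1,
                n_replicates=config.boundary_replicates, rng=rng)
            exp_counts = [v + 1 for v in null.replicate_values]
            observed.append(proj.n_exons_spanning_area)
            expected.extend(exp_counts)
            diff = proj.n_exons_spanning_area - exp_counts[0]
            if diff > 0:
                wins += 1
            elif diff < 0:
                losses += 1
            else:
                ties += 1
            rows.append({
                "site_id": site.site_id, "gene_id": gene.gene_id,
                "ligand_category": site.ligand_category,
                "area_first": area.first, "area_last": area.last,
                "n_borders_observed": proj.n_internal_borders_in_area,
                "n_exons_observed": proj.n_exons_spanning_area,
                "n_exons_expected_mean": float(np.mean(exp_counts)),
            })
    if not rows:
        report.metadata["error"] = "no data: no sites on multi-exon genes"
        return report
    per_site = pd.DataFrame(rows)
    report.tables["per_site"] = per_site
    report.metadata["n_site_areas"] = len(observed)
    report.metadata["observed_mean_exons"] = float(np.mean(observed))
    report.metadata["expected_mean_exons"] = float(np.mean(expected))
    cap = config.exon_count_cap
    obs_hist = _capped(observed, cap)
    exp_hist = _capped(expected, cap)
    dist = pd.DataFrame({
        "n_exons": [str(i) for i in range(1, cap)] + [f"{cap}+"],
        "observed": obs_hist,
        "expected": exp_hist,
    })
    report.tables["count_distribution"] = dist
    keep = (obs_hist + exp_hist) > 0
    if keep.sum() >= 2 and obs_hist.sum() > 0 and exp_hist.sum() > 0:
        report.tests.append(chi2_contingency(
            np.stack([obs_hist[keep], exp_hist[keep]])))
    else:
        report.metadata["chi2_skipped"] = (
            "observed and expected counts concentrate in a single bin")
    report.tests.append(mann_whitney_u(observed, expected))
    n_pairs = wins + losses
    if n_pairs > 0:
        sign_p = sps.binomtest(wins, n_pairs, 0.5).pvalue
        report.tests.append(TestResult(
            statistic_name="paired_sign_test",
            statistic_value=float(wins), p_value=float(sign_p), n1=n_pairs,
            extra={"n_ties_dropped": ties,
                   "direction": "observed_minus_expected"}))
    else:
        report.metadata["sign_test_skipped"] = "all pairs tied"
    cats = []
    for cat, sub in per_site.groupby("ligand_category", sort=True):
        cats.append({
            "ligand_category": cat, "n_sites": len(sub),
            "observed_mean_exons": float(sub["n_exons_observed"].mean()),
            "expected_mean_exons": float(sub["n_exons_expected_mean"].mean()),
        })
    report.tables["by_category"] = pd.DataFrame(cats)
    return report


# ---------------------------------------------------------------------------
# phases

def _phase_2x2(records: Sequence[ExonRecord], end: str) -> np.ndarray:
    """2x2 table: rows EC/ENC, columns phase-0 vs phase-1/2 at the given end."""
    attr = "phase5" if end == "5prime" else "phase3"
    tab = np.zeros((2, 2), dtype=np.int64)
    for r in records:
        row = 0 if r.label == LABEL_EC else 1
        col = 0 if getattr(r, attr) == 0 else 1
        tab[row, col] += 1
    return tab


def stage_phases(genes: Sequence[GeneModel], sites: Sequence[SiteAnnotation],
                 config: Optional[RunConfig] = None) -> AnalysisReport:
    """Junction-phase analyses on internal (non-terminal) exons.

    Produces 2x2 EC/ENC vs phase-0/non-0 contingency tables at the 5' and 3'
    exon ends, the symmetric-exon phase-pair table, the boundary-phase census
    of site codons against its permutation expectation, and a per-gene paired
    Wilcoxon on within-gene 5'-phase-0 fractions.  Chi-square p-values are
    Bonferroni-adjusted within the stage.
    """
    config = config or RunConfig()
    genes, sites = _apply_filters(genes, sites, config)
    grouped = _group_sites(genes, sites)
    multi = [g for g in sorted(genes, key=lambda g: g.gene_id) if g.n_exons >= 2]
    report = AnalysisReport(stage="phases", metadata={
        "seed": config.seed, "permutations": config.permutations,
        "terminal_exons_excluded": True,
        "n_genes": len(genes), "n_sites": len(sites),
    })
    if not multi:
        report.metadata["error"] = "no data: no internal junctions in the sample"
        return report
    per_gene_records = {g.gene_id: classify_exons(g, grouped[g.gene_id])
                        for g in multi}
    internal = [r for recs in per_gene_records.values() for r in recs
                if not r.is_terminal]
    chi2_tests: List[TestResult] = []
    # 5'/3' phase-0 contingency tables (internal exons only)
    for end in ("5prime", "3prime"):
        tab = _phase_2x2(internal, end)
        name = f"phase0_{end}"
        report.tables[name] = pd.DataFrame(
            tab, index=[LABEL_EC, LABEL_ENC],
            columns=["phase0", "phase12"]).reset_index(names="class")
        try:
            t = chi2_contingency(tab)
            chi2_tests.append(TestResult(
                statistic_name=f"chi2_{name}", statistic_value=t.statistic_value,
                p_value=t.p_value, df=t.df, n1=t.n1, n2=t.n2))
        except ValueError as exc:
            report.metadata[f"{name}_skipped"] = str(exc)
    # symmetric exons: 0-0 vs other symmetric pairs
    sym = [r for r in internal if r.symmetric]
    sym_tab = np.zeros((2, 2), dtype=np.int64)
    for r in sym:
        row = 0 if r.label == LABEL_EC else 1
        col = 0 if r.phase5 == 0 else 1
        sym_tab[row, col] += 1
    report.tables["symmetric"] = pd.DataFrame(
        sym_tab, index=[LABEL_EC, LABEL_ENC],
        columns=["sym_0_0", "sym_other"]).reset_index(names="class")
    try:
        t = chi2_contingency(sym_tab)
        chi2_tests.append(TestResult(
            statistic_name="chi2_symmetric_0_0", statistic_value=t.statistic_value,
            p_value=t.p_value, df=t.df, n1=t.n1, n2=t.n2))
    except ValueError as exc:
        report.metadata["symmetric_skipped"] = str(exc)
    # boundary-phase census of site codons, observed vs permutation-expected
    obs_counts = np.zeros(3, dtype=np.int64)
    sample = []
    for gene in multi:
        gsites = sorted(grouped[gene.gene_id], key=lambda s: s.site_id)
        kept = []
        for site in gsites:
            try:
                proj = observed_discontinuity(gene, site)
            except ValueError as exc:
                logger.warning("%s", exc)
                continue
            kept.append(site)
            for _, phase, _ in proj.boundary_phase_events:
                obs_counts[phase] += 1
        sample.append((gene, kept))
    total_obs = int(obs_counts.sum())
    report.metadata["n_boundary_events_observed"] = total_obs
    if total_obs > 0:
        perm: PhasePermutationResult = expected_phase_fractions(
            sample, n_replicates=config.permutations,
            seed=int(child_rng(config.seed, "phases").integers(2**31)),
            exclude_terminal_exon_residues=False)
        exp_frac = np.array([perm.fractions[p].mean for p in (0, 1, 2)])
        census = pd.DataFrame({
            "phase": [0, 1, 2],
            "observed_events": obs_counts,
            "observed_fraction": obs_counts / total_obs,
            "expected_fraction": exp_frac,
            "expected_mean_events": perm.mean_counts,
        })
        report.tables["site_codon_phase_census"] = census
        exp_counts = np.asarray(perm.mean_counts)
        try:
            t = chi2_contingency(np.stack([obs_counts, exp_counts]))
            chi2_tests.append(TestResult(
                statistic_name="chi2_census_obs_vs_permuted",
                statistic_value=t.statistic_value, p_value=t.p_value,
                df=t.df, n1=t.n1, n2=t.n2))
        except ValueError as exc:
            report.metadata["census_chi2_skipped"] = str(exc)
        report.metadata["observed_phase0_fraction"] = float(
            obs_counts[0] / total_obs)
        report.metadata["expected_phase0_fraction"] = float(exp_frac[0])
    else:
        report.metadata["census_skipped"] = "no boundary-associated site codons"
    # Bonferroni within the stage's chi-square family
    m = len(chi2_tests)
    report.tests.extend(t.with_correction(m) for t in chi2_tests)
    # per-gene paired Wilcoxon on within-gene 5'-phase-0 fractions
    frac_ec, frac_enc = [], []
    for gene_id in sorted(per_gene_records):
        recs = [r for r in per_gene_records[gene_id] if not r.is_terminal]
        ec = [r for r in recs if r.label == LABEL_EC]
        enc = [r for r in recs if r.label == LABEL_ENC]
        if not ec or not enc:
            continue
        frac_ec.append(np.mean([r.phase5 == 0 for r in ec]))
        frac_enc.append(np.mean([r.phase5 == 0 for r in enc]))
    report.metadata["n_genes_paired"] = len(frac_ec)
    if frac_ec:
        try:
            report.tests.append(wilcoxon_signed_rank(frac_ec, frac_enc))
        except ValueError as exc:
            report.metadata["wilcoxon_skipped"] = str(exc)
    else:
        report.metadata["wilcoxon_skipped"] = (
            "no gene has both EC and ENC internal exons")
    return report


# ---------------------------------------------------------------------------
# ligand categories

def stage_ligand_categories(genes: Sequence[GeneModel],
                            sites: Sequence[SiteAnnotation],
                            config: Optional[RunConfig] = None) -> AnalysisReport:
    """Ligand-category composition overall and among symmetric phase-0 exons.

    The second table restricts to sites at least one of whose exons is a
    symmetric 0-0 EC exon.  When buffer-ligand exclusion is enabled the same
    two tables are produced for the filtered sample.
    """
    config = config or RunConfig()
    genes = list(genes)
    sites = list(sites)
    report = AnalysisReport(stage="categories", metadata={
        "n_genes": len(genes), "n_sites": len(sites),
        "exclude_buffer_ligands": config.exclude_buffer_ligands,
    })
    if not sites or all(not s.ligand_category for s in sites):
        report.metadata["error"] = "no data: no ligand category annotations"
        return report
    by_gene = {g.gene_id: g for g in genes}
    grouped = _group_sites(genes, sites)

    def census(site_list):
        counts: Dict[str, int] = {}
        for s in site_list:
            counts[s.ligand_category] = counts.get(s.ligand_category, 0) + 1
        total = sum(counts.values())
        return pd.DataFrame([
            {"ligand_category": c, "n_sites": n,
             "fraction": n / total if total else 0.0}
            for c, n in sorted(counts.items())])

    def sym0_sites(site_list):
        out = []
        for s in site_list:
            gene = by_gene.get(s.gene_id)
            if gene is None:
                continue
            recs = classify_exons(gene, [s])
            if any(r.label == LABEL_EC and r.symmetric and r.phase5 == 0
                   for r in recs):
                out.append(s)
        return out

    valid = [s for s in sites if s.gene_id in by_gene]
    report.tables["all_sites"] = census(valid)
    report.tables["symmetric_phase0_sites"] = census(sym0_sites(valid))
    if config.exclude_buffer_ligands:
        if config.buffer_categories:
            kept = filter_buffer_ligands(valid, config.buffer_categories)
        else:
            kept = [s for s in valid if not s.is_buffer_ligand]
        report.tables["all_sites_no_buffer"] = census(kept)
        report.tables["symmetric_phase0_sites_no_buffer"] = census(sym0_sites(kept))
        report.metadata["n_sites_after_buffer_filter"] = len(kept)
    return report


# ---------------------------------------------------------------------------
# orchestration

_STAGES = {
    "lengths": stage_lengths,
    "discontinuity": stage_discontinuity,
    "phases": stage_phases,
    "categories": stage_ligand_categories,
}


def run_all(genes: Sequence[GeneModel], sites: Sequence[SiteAnnotation],
            config: Optional[RunConfig] = None,
            out_dir=None) -> Dict[str, AnalysisReport]:
    """Run every enabled stage with a shared seed; optionally write the bundle.

    Stage outputs are identical whether produced here or by calling the
    stage functions directly with the same configuration.
    """
    config = config or RunConfig()
    if not genes:
        raise ValueError("empty input: no gene models")
    reports: Dict[str, AnalysisReport] = {}
    for name in config.stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        reports[name] = _STAGES[name](genes, sites, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rep in reports.values():
            rep.write(out)
        bundle_meta = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stages": {name: rep.metadata for name, rep in reports.items()},
        }
        (out / "metadata.json").write_text(
            json.dumps(bundle_meta, indent=1, sort_keys=True) + "\n")
    return reports
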