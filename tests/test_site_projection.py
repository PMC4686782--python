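"""EC/ENC classification, site areas and observed discontinuity."""

import numpy as np
import pytest

from exonproj.gene_model import GeneModel
from exonproj.site_projection import (
    LABEL_EC,
    LABEL_ENC,
    SiteAnnotation,
    build_site_area,
    classify_exons,
    filter_buffer_ligands,
    observed_discontinuity,
    pick_representatives,
)

from conftest import (
    brute_force_borders_in_area,
    brute_force_ec_labels,
    random_gene,
)


def make_site(gene_id, residues, site_id="s1", category="amines", buffer=False):
    return SiteAnnotation(
        protein_id=f"p_{gene_id}", gene_id=gene_id, site_id=site_id,
        ligand_id="L1", ligand_category=category, residues=tuple(residues),
        is_buffer_ligand=buffer)


class TestClassifyExons:
    def test_site_in_first_exon_only(self):
        gene = GeneModel("g", (9, 9))
        records = classify_exons(gene, [make_site("g", [1])])
        assert [r.label for r in records] == [LABEL_EC, LABEL_ENC]

    def test_split_codon_marks_both_exons(self):
        gene = GeneModel("g", (4, 5))
        records = classify_exons(gene, [make_site("g", [2])])
        assert [r.label for r in records] == [LABEL_EC, LABEL_EC]

    def test_terminal_flags(self):
        gene = GeneModel("g", (9, 9, 9))
        records = classify_exons(gene, [])
        assert [r.is_terminal for r in records] == [True, False, True]

    def test_boundary_residue_flags(self):
        # residue 2 spans nt 4-6: covers exon 1's first nt (5) but not its last
        gene = GeneModel("g", (4, 5))
        records = classify_exons(gene, [make_site("g", [2])])
        assert records[1].codes_site_residue_at_5prime
        assert not records[1].codes_site_residue_at_3prime
        assert records[0].codes_site_residue_at_3prime

    def test_site_beyond_protein_is_skipped(self, caplog):
        gene = GeneModel("g", (9, 9))
        records = classify_exons(gene, [make_site("g", [99])])
        assert all(r.label == LABEL_ENC for r in records)

    def test_site_for_other_gene_raises(self):
        gene = GeneModel("g", (9, 9))
        with pytest.raises(ValueError):
            classify_exons(gene, [make_site("other", [1])])

    def test_labels_match_per_nucleotide_scan(self, rng):
        for i in range(100):
            gene = random_gene(rng, gene_id=f"r{i}", min_exons=2, max_len=60)
            n_res = gene.n_residues
            residue_sets = [
                sorted(rng.choice(n_res, size=min(4, n_res), replace=False) + 1)
                for _ in range(2)
            ]
            sites = [make_site(gene.gene_id, rs, site_id=f"s{j}")
                     for j, rs in enumerate(residue_sets)]
            records = classify_exons(gene, sites)
            expected_ec = brute_force_ec_labels(gene.exon_cds_lengths, residue_sets)
            got_ec = {r.exon_index for r in records if r.label == LABEL_EC}
            assert got_ec == expected_ec

    def test_every_exon_gets_exactly_one_label(self, rng):
        for i in range(50):
            gene = random_gene(rng, gene_id=f"r{i}", min_exons=2, max_len=60)
            sites = [make_site(gene.gene_id, [1, gene.n_residues])]
            records = classify_exons(gene, sites)
            assert len(records) == gene.n_exons
            assert all(r.label in (LABEL_EC, LABEL_ENC) for r in records)


class TestSiteArea:
    def test_multi_residue_area(self):
        area = build_site_area(make_site("g", [10, 45, 47]))
        assert (area.first, area.last) == (10, 47)
        assert area.nt_span == (28, 141)

    def test_single_residue_area(self):
        area = build_site_area(make_site("g", [5]))
        assert (area.first, area.last) == (5, 5)
        assert area.nt_span == (13, 15)

    def test_span_width_identity(self, rng):
        for _ in range(20):
            residues = sorted(rng.choice(200, size=5, replace=False) + 1)
            area = build_site_area(make_site("g", residues))
            a, b = area.nt_span
            assert b - a + 1 == 3 * (area.last - area.first + 1)


class TestObservedDiscontinuity:
    def test_site_inside_one_exon(self):
        gene = GeneModel("g", (30, 30))
        proj = observed_discontinuity(gene, make_site("g", [2, 5, 8]))
        assert proj.n_internal_borders_in_area == 0
        assert proj.n_exons_spanning_area == 1

    def test_area_straddling_one_junction(self):
        gene = GeneModel("g", (4, 5))
        proj = observed_discontinuity(gene, make_site("g", [1, 3]))
        assert proj.n_internal_borders_in_area == 1
        assert proj.n_exons_spanning_area == 2
        assert proj.exon_indices == (0, 1)

    def test_matches_enumeration_oracle(self, rng):
        for i in range(100):
            gene = random_gene(rng, gene_id=f"r{i}", min_exons=2, max_len=80)
            n_res = gene.n_residues
            residues = sorted(rng.choice(n_res, size=min(5, n_res),
                                         replace=False) + 1)
            proj = observed_discontinuity(gene, make_site(gene.gene_id, residues))
            expected = brute_force_borders_in_area(
                gene.exon_cds_lengths, residues[0], residues[-1])
            assert proj.n_internal_borders_in_area == expected
            assert proj.n_exons_spanning_area == expected + 1

    def test_adding_residue_never_shrinks_area_or_borders(self, rng):
        for i in range(50):
            gene = random_gene(rng, gene_id=f"r{i}", min_exons=2, max_len=80)
            n_res = gene.n_residues
            k = min(4, n_res - 1)
            base = sorted(rng.choice(n_res, size=k, replace=False) + 1)
            extra = int(rng.integers(1, n_res + 1))
            grown = sorted(set(base) | {extra})
            p0 = observed_discontinuity(gene, make_site(gene.gene_id, base))
            p1 = observed_discontinuity(gene, make_site(gene.gene_id, grown))
            a0 = build_site_area(make_site(gene.gene_id, base))
            a1 = build_site_area(make_site(gene.gene_id, grown))
            assert a1.first <= a0.first and a1.last >= a0.last
            assert p1.n_internal_borders_in_area >= p0.n_internal_borders_in_area

    def test_single_residue_site_spans_at_most_two_exons(self, rng):
        for i in range(50):
            gene = random_gene(rng, gene_id=f"r{i}", min_exons=2,
                               min_len=3, max_len=50)
            r = int(rng.integers(1, gene.n_residues + 1))
            proj = observed_discontinuity(gene, make_site(gene.gene_id, [r]))
            assert proj.n_exons_spanning_area in (1, 2)


class TestBufferFilter:
    def setup_method(self):
        self.sites = [
            make_site("g", [1], site_id="a", category="amines"),
            make_site("g", [2], site_id="b", category="buffer", buffer=True),
            make_site("g", [3], site_id="c", category="esters"),
            make_site("g", [4], site_id="d", category="buffer", buffer=True),
        ]

    def test_empty_exclusion_is_identity(self):
        assert filter_buffer_ligands(self.sites, []) == self.sites

    def test_all_excluded_gives_empty_list(self):
        kept = filter_buffer_ligands(self.sites, ["amines", "buffer", "esters"])
        assert kept == []

    def test_mixed_exclusion_count(self):
        kept = filter_buffer_ligands(self.sites, ["buffer"])
        assert [s.site_id for s in kept] == ["a", "c"]

    def test_unknown_category_warns_but_is_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            kept = filter_buffer_ligands(self.sites, ["solvents"])
        assert len(kept) == len(self.sites)
        assert any("solvents" in rec.message for rec in caplog.records)


def test_pick_representatives_one_per_group():
    ids = ["a", "b", "c", "d", "e"]
    groups = ["G1", "G1", "G2", "G2", "G3"]
    reps = pick_representatives(ids, groups, seed=1)
    assert len(reps) == 3
    assert set(reps) <= set(ids)
    picked_groups = [groups[ids.index(r)] for r in reps]
    assert sorted(picked_groups) == ["G1", "G2", "G3"]


def test_duplicate_residues_collapse():
    site = make_site("g", [5, 5, 3, 3, 1])
    assert site.residues == (1, 3, 5)
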