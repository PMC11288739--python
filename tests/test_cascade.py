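"""Filtration-cascade tests on hand-built fixtures."""
import pytest

from bulkmapper import (
    BulkSite,
    GeneModel,
    LinkedRegion,
    contrast_unique,
    filter_homozygous,
    restrict_to_regions,
    run_cascade,
)

T, C = "bulkJ", "bulkL"


def _site(chrom, pos, target, control, ref="A", alt="G"):
    return BulkSite(chrom, pos, ref, alt, {T: target, C: control})


class TestContrastUnique:
    def test_zero_support_rule(self):
        target = [
            _site("c1", 10, (0, 18), (18, 0)),   # absent in control: kept
            _site("c1", 20, (0, 18), (9, 9)),    # het in control: removed
            _site("c1", 30, (0, 18), (0, 20)),   # shared: removed
            _site("c1", 40, (20, 0), (20, 0)),   # no target alt support: removed
        ]
        kept = contrast_unique(target, target, T, C)
        assert [s.pos for s in kept] == [10]

    def test_site_absent_from_control_collection(self):
        target = [_site("c1", 10, (0, 18), (18, 0))]
        kept = contrast_unique(target, [], T, C)
        assert kept == target

    def test_unsorted_input_errors(self):
        sites = [_site("c1", 20, (0, 5), (5, 0)), _site("c1", 10, (0, 5), (5, 0))]
        with pytest.raises(ValueError, match="sorted"):
            contrast_unique(sites, sites, T, C)


class TestFilterHomozygous:
    @pytest.mark.parametrize(
        "counts,kept",
        [((0, 20), True), ((10, 10), False), ((1, 19), True), ((0, 4), False)],
    )
    def test_fraction_and_depth_rule(self, counts, kept):
        sites = [_site("c1", 10, counts, (5, 5))]
        assert (len(filter_homozygous(sites, T)) == 1) is kept

    def test_idempotent(self, rng):
        sites = [
            _site("c1", i + 1, (int(r), int(a)), (5, 5))
            for i, (r, a) in enumerate(rng.integers(0, 30, size=(50, 2)))
            if r + a > 0
        ]
        once = filter_homozygous(sites, T)
        assert filter_homozygous(once, T) == once


class TestRestrictToRegions:
    REGIONS = [LinkedRegion("c1", 100, 200, 5, 1.0)]

    def test_inclusive_boundaries_and_levels(self):
        sites = [
            _site("c1", 100, (0, 9), (5, 5)),
            _site("c1", 200, (0, 9), (5, 5)),
            _site("c1", 250, (0, 9), (5, 5)),
            _site("c2", 150, (0, 9), (5, 5)),
        ]
        on_chrom = restrict_to_regions(sites, self.REGIONS, "chromosome")
        assert [s.pos for s in on_chrom] == [100, 200, 250]
        in_region = restrict_to_regions(sites, self.REGIONS, "region")
        assert [s.pos for s in in_region] == [100, 200]

    def test_exact_subset_on_mixed_fixture(self, rng):
        regions = [
            LinkedRegion("c1", 100, 200, 5, 1.0),
            LinkedRegion("c2", 500, 600, 5, 1.0),
        ]
        inside = [("c1", 150), ("c1", 100), ("c2", 600), ("c2", 501)]
        outside = [("c1", 99), ("c1", 201), ("c2", 499), ("c3", 150),
                   ("c2", 1000), ("c1", 5000)]
        sites = sorted(
            (_site(c, p, (0, 9), (5, 5)) for c, p in inside + outside),
            key=lambda s: (s.chrom, s.pos),
        )
        kept = restrict_to_regions(sites, regions, "region")
        assert sorted((s.chrom, s.pos) for s in kept) == sorted(inside)

    def test_empty_regions_error(self):
        with pytest.raises(ValueError):
            restrict_to_regions([], [], "region")


class TestRunCascade:
    """Hand-enumerable fixture: one planted nonsense variant in an HC gene,
    one missense decoy in an LC gene, one intergenic decoy, all inside the
    mapped region, plus a shared site and a synonymous HC variant."""

    # HC gene 100-163: UTR 100-105, CDS 106-132 (9 codons), UTR 133-163
    # CDS: ATG GCT TGG TCC AAA GAA CTG TGG TGA
    CDS = "ATGGCTTGGTCCAAAGAACTGTGGTGA"

    def _fixture(self):
        genome_c1 = (
            "A" * 99 + "TTTTTT" + self.CDS + "C" * 31
            + "G" * 63  # spacer to 226
            + "TTTTTT" + self.CDS + "C" * 31  # LC gene at 227-290
            + "A" * 300
        )
        genes = [
            GeneModel("hcGene", "c1", "+", exons=((100, 163),),
                      cds=((106, 132),), confidence="HC"),
            GeneModel("lcGene", "c1", "+", exons=((227, 290),),
                      cds=((233, 259),), confidence="LC"),
        ]
        genome = {"c1": genome_c1}
        regions = [LinkedRegion("c1", 50, 350, 10, 1.0)]
        # nonsense in hcGene: codon 3 TGG->TGA, third base at 106+8=114
        sites = [
            _site("c1", 114, (0, 20), (19, 0), ref="G", alt="A"),
            # missense decoy in lcGene: codon 4 TCC->TTC at 233+10=243
            _site("c1", 243, (1, 19), (22, 0), ref="C", alt="T"),
            # synonymous in hcGene: codon 2 GCT->GCC at 106+5=111
            _site("c1", 111, (0, 18), (20, 0), ref="T", alt="C"),
            # homozygous intergenic decoy inside the region
            _site("c1", 320, (0, 15), (18, 0)),
            # shared polymorphism (removed by contrast)
            _site("c1", 130, (0, 20), (10, 10), ref="A", alt="C"),
            # heterozygous unique site (removed by homozygosity)
            _site("c1", 340, (10, 10), (20, 0)),
            # homozygous unique site on an unmapped chromosome
            _site("c2", 77, (0, 16), (21, 0)),
        ]
        sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
        return sites, regions, genes, genome

    def test_levels_and_final_candidate(self):
        sites, regions, genes, genome = self._fixture()
        report = run_cascade(sites, sites, T, C, regions, genes, genome)
        by_name = {lv.name: lv for lv in report.levels}
        assert by_name["unique_alleles_all"].allele_count == 6
        assert by_name["homozygous_all"].allele_count == 5
        assert by_name["homozygous_mapped_chromosome"].allele_count == 4
        assert by_name["homozygous_mapped_region"].allele_count == 4
        assert by_name["homozygous_in_genes"].allele_count == 3
        assert by_name["genes_with_aa_change"].allele_count == 2
        assert by_name["genes_with_aa_change"].gene_count == 2
        assert by_name["hc_genes_with_aa_change"].allele_count == 1
        assert by_name["hc_genes_with_aa_change"].gene_count == 1
        (candidate,) = report.candidates
        assert candidate.gene_id == "hcGene"
        assert candidate.effect.category.value == "nonsense"

    def test_synonymous_dropped_at_aa_change_level(self):
        sites, regions, genes, genome = self._fixture()
        report = run_cascade(sites, sites, T, C, regions, genes, genome)
        assert report.level("homozygous_in_genes").allele_count > report.level(
            "genes_with_aa_change"
        ).allele_count
        assert all(
            c.effect.category.value != "synonymous" for c in report.candidates
        )

    def test_empty_contrast_gives_all_zero(self):
        sites, regions, genes, genome = self._fixture()
        # make every alt shared: control gets alt support everywhere
        shared = [
            BulkSite(s.chrom, s.pos, s.ref_allele, s.alt_allele,
                     {T: s.counts[T], C: (5, 5)})
            for s in sites
        ]
        report = run_cascade(shared, shared, T, C, regions, genes, genome)
        assert all(lv.allele_count == 0 for lv in report.levels)
        assert report.candidates == ()

    def test_composition_equals_staged_application(self):
        sites, regions, genes, genome = self._fixture()
        report = run_cascade(sites, sites, T, C, regions, genes, genome)
        staged = contrast_unique(sites, sites, T, C)
        staged = filter_homozygous(staged, T)
        staged = restrict_to_regions(staged, regions, "chromosome")
        staged = restrict_to_regions(staged, regions, "region")
        assert report.level("homozygous_mapped_region").allele_count == len(staged)

    def test_counts_monotone(self):
        sites, regions, genes, genome = self._fixture()
        report = run_cascade(sites, sites, T, C, regions, genes, genome)
        counts = [lv.allele_count for lv in report.levels]
        assert counts == sorted(counts, reverse=True)
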