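"""Coding-effect classifier tests, including the full-translation oracle."""
import numpy as np
import pytest

from bulkmapper import (
    BulkSite,
    CdsLengthError,
    EffectCategory,
    GeneModel,
    VariantEffect,
    classify_variant,
    protein_change_string,
)
from oracles import oracle_classify_snv, random_gene, revcomp


def _snv(chrom, pos, ref, alt):
    return BulkSite(chrom, pos, ref, alt, {"t": (0, 10), "c": (10, 0)})


@pytest.fixture()
def simple_gene():
    """Plus-strand gene: 6 bp 5'UTR, two CDS exons split mid-codon, 6 bp 3'UTR.

    layout (1-based): 1-10 flank, 11-16 UTR, 17-30 CDS part 1 (14 bp),
    31-40 intron, 41-53 CDS part 2 (13 bp), 54-59 UTR.  Codon 5 (AAA)
    spans the junction (bases 29, 30, 41).
    CDS = ATG GCT TGG TCC AAA GAA CTG TGG TGA (27 bp, protein MAWSKELW*)
    """
    cds = "ATGGCTTGGTCCAAAGAACTGTGGTGA"
    flank = "ACGTACGTAC"
    utr5, utr3 = "TTTTTT", "CCCCCC"
    intron = "GTAGCTAGAG"
    seq = flank + utr5 + cds[:14] + intron + cds[14:] + utr3 + flank
    genome = {"g1": seq}
    gene = GeneModel(
        gene_id="G1", chrom="g1", strand="+",
        exons=((11, 30), (41, 59)),
        cds=((17, 30), (41, 53)),
    )
    return gene, genome


class TestSnvClasses:
    def test_tgg_to_tga_is_nonsense(self, simple_gene):
        gene, genome = simple_gene
        # codon 3 (TGG) third base sits at genomic 25; G->A makes TGA
        effect = classify_variant(_snv("g1", 25, "G", "A"), gene, genome)
        assert effect.category is EffectCategory.nonsense
        assert protein_change_string(effect) == "W3*"

    def test_missense_with_residue_coordinates(self, simple_gene):
        gene, genome = simple_gene
        # codon 4 (TCC, Ser) second base at genomic 27; C->T gives TTC (Phe)
        effect = classify_variant(_snv("g1", 27, "C", "T"), gene, genome)
        assert effect.category is EffectCategory.missense
        assert (effect.ref_aa, effect.protein_pos, effect.alt_aa) == ("S", 4, "F")

    def test_synonymous(self, simple_gene):
        gene, genome = simple_gene
        # codon 2 GCT -> GCC (both Ala); third base at genomic 22
        effect = classify_variant(_snv("g1", 22, "T", "C"), gene, genome)
        assert effect.category is EffectCategory.synonymous

    def test_start_loss(self, simple_gene):
        gene, genome = simple_gene
        effect = classify_variant(_snv("g1", 17, "A", "G"), gene, genome)
        assert effect.category is EffectCategory.start_loss

    def test_stop_loss(self, simple_gene):
        gene, genome = simple_gene
        # final codon TGA at genomic 51-53; A->G gives TGG (Trp)
        effect = classify_variant(_snv("g1", 53, "A", "G"), gene, genome)
        assert effect.category is EffectCategory.stop_loss

    def test_split_codon_across_intron(self, simple_gene):
        gene, genome = simple_gene
        # codon 5 (AAA, Lys) spans the junction; its last base sits at 41
        effect = classify_variant(_snv("g1", 41, "A", "T"), gene, genome)
        assert effect.category is EffectCategory.missense
        assert effect.protein_pos == 5
        assert (effect.ref_aa, effect.alt_aa) == ("K", "N")


class TestPositionalClasses:
    @pytest.mark.parametrize(
        "pos,category",
        [
            (5, EffectCategory.intergenic),
            (13, EffectCategory.utr),
            (57, EffectCategory.utr),
            (36, EffectCategory.intronic),
            (31, EffectCategory.splice_region),
            (32, EffectCategory.splice_region),
            (39, EffectCategory.splice_region),
            (40, EffectCategory.splice_region),
            (34, EffectCategory.intronic),
        ],
    )
    def test_classes(self, simple_gene, pos, category):
        gene, genome = simple_gene
        base = genome["g1"][pos - 1]
        alt = "A" if base != "A" else "G"
        effect = classify_variant(_snv("g1", pos, base, alt), gene, genome)
        assert effect.category is category


class TestIndels:
    def test_one_bp_deletion_is_frameshift(self, simple_gene):
        gene, genome = simple_gene
        ref = genome["g1"][19:21]  # anchored at 20, deletes base 21 (CDS)
        site = BulkSite("g1", 20, ref, ref[0], {"t": (0, 10), "c": (10, 0)})
        assert classify_variant(site, gene, genome).category is EffectCategory.frameshift

    def test_three_bp_deletion_is_inframe(self, simple_gene):
        gene, genome = simple_gene
        ref = genome["g1"][19:23]  # deletes bases 21-23
        site = BulkSite("g1", 20, ref, ref[0], {"t": (0, 10), "c": (10, 0)})
        assert classify_variant(site, gene, genome).category is EffectCategory.inframe_indel

    def test_insertion_frameshift(self, simple_gene):
        gene, genome = simple_gene
        base = genome["g1"][19]
        site = BulkSite("g1", 20, base, base + "TT", {"t": (0, 10), "c": (10, 0)})
        assert classify_variant(site, gene, genome).category is EffectCategory.frameshift

    def test_intronic_deletion_stays_positional(self, simple_gene):
        gene, genome = simple_gene
        ref = genome["g1"][34:37]  # deletes 36-37, intron interior
        site = BulkSite("g1", 35, ref, ref[0], {"t": (0, 10), "c": (10, 0)})
        assert classify_variant(site, gene, genome).category is EffectCategory.intronic


class TestContracts:
    def test_cds_length_not_multiple_of_three_refused(self):
        genome = {"g1": "A" * 10 + "ATGGC" + "A" * 10}
        gene = GeneModel("bad", "g1", "+", exons=((11, 15),), cds=((11, 15),))
        with pytest.raises(CdsLengthError):
            classify_variant(_snv("g1", 12, "T", "C"), gene, genome)

    def test_chromosome_mismatch(self, simple_gene):
        gene, genome = simple_gene
        with pytest.raises(ValueError):
            classify_variant(_snv("g2", 25, "G", "A"), gene, genome)

    def test_reference_mismatch_detected(self, simple_gene):
        gene, genome = simple_gene
        with pytest.raises(ValueError, match="mismatch"):
            classify_variant(_snv("g1", 25, "T", "A"), gene, genome)

    def test_protein_change_string(self):
        eff = VariantEffect(EffectCategory.nonsense, 291, "W", "*")
        assert protein_change_string(eff) == "W291*"
        with pytest.raises(ValueError):
            protein_change_string(VariantEffect(EffectCategory.frameshift))

    def test_residue_field_invariant(self):
        with pytest.raises(ValueError):
            VariantEffect(EffectCategory.intronic, protein_pos=4, ref_aa="A",
                          alt_aa="T")


class TestOracleAgreement:
    def test_random_coding_snvs_match_full_translation_oracle(self, rng):
        """Category and residue change agree with rebuilding and translating
        the complete CDS on random genes of both strands."""
        for _ in range(120):
            gene, genome, cds_positions = random_gene(rng)
            pos = int(cds_positions[int(rng.integers(0, len(cds_positions)))])
            ref = genome[gene.chrom][pos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            site = _snv(gene.chrom, pos, ref, alt)
            effect = classify_variant(site, gene, genome)
            category, ppos, ref_aa, alt_aa = oracle_classify_snv(
                site, gene, genome, cds_positions
            )
            assert effect.category.value == category
            assert effect.protein_pos == ppos
            assert (effect.ref_aa, effect.alt_aa) == (ref_aa, alt_aa)

    def test_strand_mirror_invariance(self, simple_gene):
        """The minus-strand mirror of a gene yields the same protein-level
        classification for the mirrored variant."""
        gene, genome = simple_gene
        seq = genome["g1"]
        n = len(seq)
        mirror_genome = {"g1": revcomp(seq)}

        def mirror_iv(iv):
            s, e = iv
            return (n - e + 1, n - s + 1)

        mirror_gene = GeneModel(
            gene_id="G1m", chrom="g1", strand="-",
            exons=tuple(sorted(mirror_iv(e) for e in gene.exons)),
            cds=tuple(sorted(mirror_iv(c) for c in gene.cds)),
        )
        for pos, ref, alt in [(25, "G", "A"), (27, "C", "T"), (22, "T", "C")]:
            fwd = classify_variant(_snv("g1", pos, ref, alt), gene, genome)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            mpos = n - pos + 1
            rev = classify_variant(
                _snv("g1", mpos, comp[ref], comp[alt]), mirror_gene, mirror_genome
            )
            assert fwd == rev
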