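"""Minimal coding-effect classifier.

Given a variant, a gene model and the genome sequence, decide how the
encoded protein changes: synonymous / missense / nonsense / stop-loss /
start-loss for SNVs in CDS, frameshift or in-frame for coding indels, and
positional classes (UTR, intronic, splice region, intergenic) otherwise.
Translation uses the standard genetic code; the annotated CDS is assumed
to start at its first codon and to include the stop codon, and its total
length must be a multiple of three (otherwise the classifier refuses).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

from Bio.Seq import Seq

from .model import BulkSite, GeneModel, get_sequence

#: intron bases at each junction reported as splice_region
SPLICE_REGION_BP = 2

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class EffectCategory(str, Enum):
    intergenic = "intergenic"
    intronic = "intronic"
    utr = "utr"
    synonymous = "synonymous"
    missense = "missense"
    nonsense = "nonsense"
    stop_loss = "stop_loss"
    start_loss = "start_loss"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    splice_region = "splice_region"


#: categories counted as altering the amino acid sequence in the cascade
PROTEIN_ALTERING = frozenset(
    {
        EffectCategory.missense,
        EffectCategory.nonsense,
        EffectCategory.stop_loss,
        EffectCategory.start_loss,
        EffectCategory.frameshift,
        EffectCategory.inframe_indel,
    }
)


class CdsLengthError(ValueError):
    """CDS length is not a multiple of three."""


@dataclass(frozen=True)
class VariantEffect:
    category: EffectCategory
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def __post_init__(self) -> None:
        residue_cats = {
            EffectCategory.synonymous,
            EffectCategory.missense,
            EffectCategory.nonsense,
            EffectCategory.stop_loss,
            EffectCategory.start_loss,
        }
        has_residues = self.protein_pos is not None
        if has_residues != (self.category in residue_cats):
            raise ValueError(
                f"residue fields {'required' if self.category in residue_cats else 'forbidden'} "
                f"for category {self.category.value}"
            )


def protein_change_string(effect: VariantEffect) -> str:
    """Render a residue change as e.g. "S212F" or "W291*"."""
    if effect.protein_pos is None:
        raise ValueError(
            f"no protein change string for category {effect.category.value}"
        )
    return f"{effect.ref_aa}{effect.protein_pos}{effect.alt_aa}"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _cds_genomic_positions(gene: GeneModel) -> List[int]:
    """Genomic positions of CDS bases in transcript (5'->3') order."""
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos[::-1] if gene.strand == "-" else pos


def _check_cds(gene: GeneModel) -> None:
    if gene.cds_length % 3 != 0:
        raise CdsLengthError(
            f"gene {gene.gene_id}: CDS length {gene.cds_length} is not a "
            f"multiple of 3"
        )


def _positional_category(gene: GeneModel, pos: int) -> EffectCategory:
    """Classify a position that is not inside the CDS."""
    if not gene.contains(pos):
        return EffectCategory.intergenic
    for s, e in gene.exons:
        if s <= pos <= e:
            return EffectCategory.utr
    # intronic; splice region if within SPLICE_REGION_BP of a junction
    for i, (s, e) in enumerate(gene.exons):
        if i > 0 and s - SPLICE_REGION_BP <= pos < s:
            return EffectCategory.splice_region
        if i < len(gene.exons) - 1 and e < pos <= e + SPLICE_REGION_BP:
            return EffectCategory.splice_region
    return EffectCategory.intronic


def _in_cds(gene: GeneModel, pos: int) -> bool:
    return any(s <= pos <= e for s, e in gene.cds)


def _classify_snv(site: BulkSite, gene: GeneModel, genome) -> VariantEffect:
    _check_cds(gene)
    cds_pos = _cds_genomic_positions(gene)
    idx = cds_pos.index(site.pos)
    codon_i, offset = divmod(idx, 3)
    codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
    bases = [get_sequence(genome, gene.chrom, p, p) for p in codon_positions]
    ref_base_plus = get_sequence(genome, gene.chrom, site.pos, site.pos)
    if ref_base_plus != site.ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at {site.chrom}:{site.pos}: "
            f"VCF {site.ref_allele!r} vs genome {ref_base_plus!r}"
        )
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = site.alt_allele.upper().translate(_COMPLEMENT)
    else:
        alt_base = site.alt_allele.upper()
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    protein_pos = codon_i + 1
    if ref_aa == alt_aa:
        category = EffectCategory.synonymous
    elif codon_i == 0 and ref_codon == "ATG":
        category = EffectCategory.start_loss
    elif alt_aa == "*":
        category = EffectCategory.nonsense
    elif ref_aa == "*":
        category = EffectCategory.stop_loss
    else:
        category = EffectCategory.missense
    return VariantEffect(
        category=category, protein_pos=protein_pos, ref_aa=ref_aa, alt_aa=alt_aa
    )


def _classify_indel(site: BulkSite, gene: GeneModel, genome) -> VariantEffect:
    ref, alt = site.ref_allele.upper(), site.alt_allele.upper()
    if len(ref) > 1 and len(alt) > 1:
        raise ValueError(
            f"unsupported complex allele at {site.chrom}:{site.pos} "
            f"({ref}>{alt}); only simple anchored indels are classified"
        )
    # anchored VCF convention: first base shared, remainder inserted/deleted
    deleted_span: Optional[Tuple[int, int]] = None
    inserted_len = 0
    if len(ref) > len(alt):
        deleted_span = (site.pos + 1, site.pos + len(ref) - 1)
    else:
        inserted_len = len(alt) - len(ref)

    del_in_cds = 0
    if deleted_span is not None:
        ds, de = deleted_span
        for s, e in gene.cds:
            del_in_cds += max(0, min(e, de) - max(s, ds) + 1)
    # an insertion lands in the CDS when its anchor base is a CDS base
    ins_in_cds = inserted_len if _in_cds(gene, site.pos) else 0

    if del_in_cds == 0 and ins_in_cds == 0:
        # does not touch coding bases: classify by position
        probe = deleted_span[0] if deleted_span is not None else site.pos
        return VariantEffect(category=_positional_category(gene, probe))
    _check_cds(gene)
    net = ins_in_cds - del_in_cds
    if net % 3 != 0:
        return VariantEffect(category=EffectCategory.frameshift)
    return VariantEffect(category=EffectCategory.inframe_indel)


def classify_variant(site: BulkSite, gene: GeneModel, genome) -> VariantEffect:
    """Classify the protein-level effect of ``site`` on ``gene``.

    ``genome`` is a chromosome-name-indexed sequence store (dict of strings
    or ``pyfaidx.Fasta``).
    """
    if site.chrom != gene.chrom:
        raise ValueError(
            f"variant on {site.chrom} cannot be classified against gene "
            f"{gene.gene_id} on {gene.chrom}"
        )
    if site.is_snp:
        if _in_cds(gene, site.pos):
            return _classify_snv(site, gene, genome)
        return VariantEffect(category=_positional_category(gene, site.pos))
    return _classify_indel(site, gene, genome)
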