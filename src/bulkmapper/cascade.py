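"""Candidate filtration cascade.

Starting from the full variant set of the target bulk, variants are
narrowed in seven ordered levels:

1. unique alleles (alt supported in the target bulk, zero alt support in
   the control bulk at the same site),
2. homozygous alleles (read-count based: alt fraction and depth cutoffs),
3. homozygous alleles on a mapped chromosome,
4. homozygous alleles inside a mapped (linked) region,
5. homozygous alleles within gene bodies,
6. variants altering the amino acid sequence, counted as distinct genes,
7. the subset of those genes that are high-confidence models.

Counts are recorded at every level; they are non-increasing by
construction.  Because the two mutant bulks share the same parental
cross, level 1 removes nearly all natural polymorphism and the cascade
converges on the induced, phenotype-linked mutations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .add_mapping import LinkedRegion
from .effects import (
    PROTEIN_ALTERING,
    VariantEffect,
    classify_variant,
)
from .model import BulkSite, GeneModel

logger = logging.getLogger(__name__)

LEVEL_NAMES = (
    "unique_alleles_all",
    "homozygous_all",
    "homozygous_mapped_chromosome",
    "homozygous_mapped_region",
    "homozygous_in_genes",
    "genes_with_aa_change",
    "hc_genes_with_aa_change",
)


@dataclass(frozen=True)
class CascadeLevel:
    name: str
    allele_count: int
    gene_count: Optional[int] = None


@dataclass(frozen=True)
class Candidate:
    site: BulkSite
    gene_id: str
    confidence: str
    effect: VariantEffect


@dataclass(frozen=True)
class CascadeReport:
    levels: Tuple[CascadeLevel, ...]
    candidates: Tuple[Candidate, ...]

    def __post_init__(self) -> None:
        counts = [lv.allele_count for lv in self.levels]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("cascade allele counts must be non-increasing")

    def level(self, name: str) -> CascadeLevel:
        for lv in self.levels:
            if lv.name == name:
                return lv
        raise KeyError(name)


def _check_sorted(sites: Sequence[BulkSite], label: str) -> None:
    keys = [(s.chrom, s.pos) for s in sites]
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in keys:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        if any(b < a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{label} sites are not sorted by (chrom, pos)")


def contrast_unique(
    target_sites: Sequence[BulkSite],
    control_sites: Sequence[BulkSite],
    target_bulk: str,
    control_bulk: str,
) -> List[BulkSite]:
    """Alleles private to the target bulk.

    A target site is retained when its alt allele has read support in the
    target bulk and zero supporting reads at the same (chrom, pos, ref,
    alt) in the control bulk — including sites absent from the control
    collection entirely.
    """
    _check_sorted(target_sites, "target")
    _check_sorted(control_sites, "control")
    control_alt: Dict[Tuple[str, int, str, str], int] = {}
    for s in control_sites:
        key = (s.chrom, s.pos, s.ref_allele, s.alt_allele)
        control_alt[key] = control_alt.get(key, 0) + s.counts[control_bulk][1]
    kept = []
    for s in target_sites:
        if s.counts[target_bulk][1] < 1:
            continue
        key = (s.chrom, s.pos, s.ref_allele, s.alt_allele)
        if control_alt.get(key, 0) == 0:
            kept.append(s)
    logger.info(
        "contrast_unique(%s vs %s): %d -> %d sites",
        target_bulk, control_bulk, len(target_sites), len(kept),
    )
    return kept


def filter_homozygous(
    sites: Sequence[BulkSite],
    bulk: str,
    min_alt_fraction: float = 0.9,
    min_depth: int = 5,
) -> List[BulkSite]:
    """Read-count homozygosity: depth >= min_depth and alt fraction >= cutoff."""
    kept = [
        s
        for s in sites
        if s.depth(bulk) >= min_depth
        and s.alt_fraction(bulk) >= min_alt_fraction
    ]
    logger.info(
        "filter_homozygous(%s): %d -> %d sites (frac >= %g, depth >= %d)",
        bulk, len(sites), len(kept), min_alt_fraction, min_depth,
    )
    return kept


def restrict_to_regions(
    sites: Sequence[BulkSite],
    regions: Sequence[LinkedRegion],
    level: str,
) -> List[BulkSite]:
    """Restrict sites to mapped chromosomes ("chromosome") or regions ("region").

    Region boundaries are inclusive on both sides.
    """
    if level not in ("chromosome", "region"):
        raise ValueError(f"level must be 'chromosome' or 'region', got {level!r}")
    if level == "region" and not regions:
        raise ValueError("cannot restrict to regions: no linked regions given")
    if level == "chromosome":
        chroms = {r.chrom for r in regions}
        kept = [s for s in sites if s.chrom in chroms]
    else:
        kept = [
            s
            for s in sites
            if any(
                r.chrom == s.chrom and r.start <= s.pos <= r.end for r in regions
            )
        ]
    logger.info(
        "restrict_to_regions(%s): %d -> %d sites", level, len(sites), len(kept)
    )
    return kept


def _genes_overlapping(
    genes: Sequence[GeneModel], site: BulkSite
) -> List[GeneModel]:
    return [
        g for g in genes if g.chrom == site.chrom and g.contains(site.pos)
    ]


def run_cascade(
    target_sites: Sequence[BulkSite],
    control_sites: Sequence[BulkSite],
    target_bulk: str,
    control_bulk: str,
    regions: Sequence[LinkedRegion],
    genes: Sequence[GeneModel],
    genome,
    min_alt_fraction: float = 0.9,
    min_depth: int = 5,
) -> CascadeReport:
    """Run the full seven-level filtration cascade for one bulk.

    ``regions`` are the linked regions called by ADD mapping with the same
    target/control orientation.  When no region was called, levels 3-7
    are empty by definition (there is no mapped chromosome).
    """
    levels: List[CascadeLevel] = []

    unique = contrast_unique(target_sites, control_sites, target_bulk, control_bulk)
    levels.append(CascadeLevel("unique_alleles_all", len(unique)))

    homozygous = filter_homozygous(unique, target_bulk, min_alt_fraction, min_depth)
    levels.append(CascadeLevel("homozygous_all", len(homozygous)))

    if regions:
        on_chrom = restrict_to_regions(homozygous, regions, "chromosome")
        in_region = restrict_to_regions(on_chrom, regions, "region")
    else:
        on_chrom, in_region = [], []
    levels.append(CascadeLevel("homozygous_mapped_chromosome", len(on_chrom)))
    levels.append(CascadeLevel("homozygous_mapped_region", len(in_region)))

    in_genes: List[Tuple[BulkSite, List[GeneModel]]] = []
    for site in in_region:
        hits = _genes_overlapping(genes, site)
        if hits:
            in_genes.append((site, hits))
    levels.append(
        CascadeLevel(
            "homozygous_in_genes",
            len(in_genes),
            gene_count=len({g.gene_id for _, hits in in_genes for g in hits}),
        )
    )

    altering: List[Candidate] = []
    for site, hits in in_genes:
        for gene in hits:
            effect = classify_variant(site, gene, genome)
            if effect.category in PROTEIN_ALTERING:
                altering.append(
                    Candidate(
                        site=site,
                        gene_id=gene.gene_id,
                        confidence=gene.confidence,
                        effect=effect,
                    )
                )
    levels.append(
        CascadeLevel(
            "genes_with_aa_change",
            len({(c.site.chrom, c.site.pos, c.site.alt_allele) for c in altering}),
            gene_count=len({c.gene_id for c in altering}),
        )
    )

    hc = [c for c in altering if c.confidence == "HC"]
    levels.append(
        CascadeLevel(
            "hc_genes_with_aa_change",
            len({(c.site.chrom, c.site.pos, c.site.alt_allele) for c in hc}),
            gene_count=len({c.gene_id for c in hc}),
        )
    )

    return CascadeReport(levels=tuple(levels), candidates=tuple(hc))
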