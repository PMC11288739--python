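"""Core domain types shared across the pipeline.

Coordinates are 1-based and inclusive throughout, matching the native
conventions of both VCF and GFF3.  A :class:`BulkSite` is the atom of the
whole analysis: one biallelic variant with per-bulk (ref, alt) read counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple


class GeneStructureError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class BulkSite:
    """One biallelic variant with per-bulk allele depths.

    Parameters
    ----------
    chrom, pos
        Chromosome name and 1-based position.
    ref_allele, alt_allele
        VCF-style alleles.  SNVs have single-base ref and alt; anchored
        indels may carry a multi-base allele on either side.
    counts
        Mapping from bulk (sample) name to ``(ref_reads, alt_reads)``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: Mapping[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        for bulk, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValueError(
                    f"negative read count for bulk {bulk!r} at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def is_snp(self) -> bool:
        """True for single-nucleotide substitutions (ADD mapping uses only these)."""
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def depth(self, bulk: str) -> int:
        r, a = self.counts[bulk]
        return r + a

    def alt_fraction(self, bulk: str) -> float:
        r, a = self.counts[bulk]
        d = r + a
        if d == 0:
            raise ValueError(
                f"alt fraction undefined at zero depth ({self.chrom}:{self.pos}, "
                f"bulk {bulk!r})"
            )
        return a / d

    def add(self, bulk: str) -> float:
        """Allele depth difference |ref - alt| / (ref + alt) in one bulk."""
        r, a = self.counts[bulk]
        if r + a == 0:
            raise ValueError(
                f"allele depth difference undefined at zero depth "
                f"({self.chrom}:{self.pos}, bulk {bulk!r})"
            )
        return abs(r - a) / (r + a)


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene (single transcript).

    ``exons`` and ``cds`` are ordered lists of 1-based inclusive
    ``(start, end)`` intervals in ascending genomic coordinates regardless
    of strand.  ``confidence`` is the annotation class, "HC"
    (high-confidence) or "LC".
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...]
    confidence: str = "HC"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneStructureError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise GeneStructureError(f"gene {self.gene_id}: no exons")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(self, "cds", tuple(tuple(c) for c in self.cds))
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise GeneStructureError(
                    f"gene {self.gene_id}: exon start {s} > end {e}"
                )
            if s <= prev_end:
                raise GeneStructureError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at {s}"
                )
            prev_end = e
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise GeneStructureError(
                    f"gene {self.gene_id}: CDS interval ({s}, {e}) not contained "
                    f"in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start..end] (1-based inclusive) as an upper-case string.

    ``genome`` may be a plain ``dict`` of chromosome strings or a
    ``pyfaidx.Fasta`` object (anything whose item access supports slicing).
    """
    record = genome[chrom]
    if isinstance(record, str):
        seq = record[start - 1 : end]
    else:  # pyfaidx.FastaRecord or similar
        seq = str(record[start - 1 : end])
    return seq.upper()
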