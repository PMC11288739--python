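"""Readers and writers for the standard formats the pipeline touches.

VCF access goes through pysam, GFF3 through gffutils (in-memory database),
tabular outputs through pandas.  Everything stays in 1-based inclusive
coordinates.
"""
from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
import pysam

from .model import BulkSite, GeneModel, GeneStructureError

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


def read_biallelic_sites(
    vcf_path: str,
    bulk_names: Tuple[str, str],
    stats: Optional[dict] = None,
) -> List[BulkSite]:
    """Read biallelic variants with per-sample allele depths for two bulks.

    Multiallelic records and records lacking the AD field in either sample
    are skipped (counted in ``stats`` and logged).  Indels are retained but
    flagged via :attr:`BulkSite.is_snp` so ADD mapping can exclude them.

    Parameters
    ----------
    vcf_path
        Path to a VCF 4.x file (plain or bgzipped).
    bulk_names
        The two sample names, (target, control) in any fixed order.
    stats
        Optional dict; filled with ``n_records``, ``n_retained``,
        ``n_skipped_multiallelic`` and ``n_skipped_missing_ad``.

    Returns
    -------
    list of BulkSite ordered by (chrom, pos) with chromosomes in header order.
    """
    if not os.path.exists(vcf_path):
        raise FileNotFoundError(vcf_path)
    bulk_a, bulk_b = bulk_names
    counters = {
        "n_records": 0,
        "n_retained": 0,
        "n_skipped_multiallelic": 0,
        "n_skipped_missing_ad": 0,
    }
    sites: List[BulkSite] = []
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        for name in (bulk_a, bulk_b):
            if name not in samples:
                raise VcfParseError(
                    f"sample {name!r} not in VCF header (samples: {samples})"
                )
        contig_rank = {c: i for i, c in enumerate(vcf.header.contigs)}
        for rec in vcf:
            counters["n_records"] += 1
            if rec.alts is None or len(rec.alts) != 1:
                counters["n_skipped_multiallelic"] += 1
                continue
            counts: Dict[str, Tuple[int, int]] = {}
            ok = True
            for name in (bulk_a, bulk_b):
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                    ok = False
                    break
                counts[name] = (int(ad[0]), int(ad[1]))
            if not ok:
                counters["n_skipped_missing_ad"] += 1
                continue
            try:
                sites.append(
                    BulkSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=rec.alts[0],
                        counts=counts,
                    )
                )
            except ValueError as exc:
                raise VcfParseError(
                    f"malformed record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            counters["n_retained"] += 1
    sites.sort(key=lambda s: (contig_rank.get(s.chrom, len(contig_rank)), s.chrom, s.pos))
    logger.info(
        "read %d records from %s: %d retained, %d multiallelic skipped, "
        "%d missing-AD skipped",
        counters["n_records"], vcf_path, counters["n_retained"],
        counters["n_skipped_multiallelic"], counters["n_skipped_missing_ad"],
    )
    if stats is not None:
        stats.update(counters)
    return sites


def write_biallelic_sites(
    sites: Sequence[BulkSite],
    bulk_names: Tuple[str, str],
    contigs: Sequence[Tuple[str, int]],
    out_path: str,
) -> None:
    """Write BulkSites as a two-sample VCF with AD per sample."""
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for name in bulk_names:
        header.add_sample(name)
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for name in bulk_names:
                r, a = site.counts[name]
                rec.samples[name]["AD"] = (r, a)
            out.write(rec)


def read_gene_models(
    gff_path: str,
    confidence_attribute: str = "confidence",
    hc_value: str = "HC",
) -> List[GeneModel]:
    """Parse gene models from GFF3.

    One mRNA per gene is used (the first by file order, with a warning when
    several exist).  Confidence is "HC" iff the gene's
    ``confidence_attribute`` equals ``hc_value``, else "LC".
    """
    if not os.path.exists(gff_path):
        raise FileNotFoundError(gff_path)
    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            logger.warning("gene %s has no mRNA; skipped", gene.id)
            continue
        if len(mrnas) > 1:
            logger.warning(
                "gene %s has %d mRNAs; using the first (%s)",
                gene.id, len(mrnas), mrnas[0].id,
            )
        mrna = mrnas[0]
        exons = sorted(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="CDS")
        )
        for s, e in cds:
            if s < gene.start or e > gene.end:
                raise GeneStructureError(
                    f"gene {gene.id}: CDS ({s}, {e}) outside gene span "
                    f"({gene.start}, {gene.end})"
                )
        conf_values = gene.attributes.get(confidence_attribute, [])
        confidence = "HC" if hc_value in conf_values else "LC"
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons) if exons else tuple(cds),
                cds=tuple(cds),
                confidence=confidence,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Tabular outputs


def write_add_track(tracks, out_path: str) -> None:
    """Serialize one or more ADD tracks as TSV.

    Columns: chrom, pos, add, running_median; fixed 6-decimal formatting so
    the file round-trips to equal values at 1e-6.
    """
    from .add_mapping import AddTrack  # local import to avoid cycle

    if isinstance(tracks, AddTrack):
        tracks = [tracks]
    rows = []
    for track in tracks:
        rm = track.running_medians
        for i, pos in enumerate(track.positions):
            rows.append(
                (
                    track.chrom,
                    int(pos),
                    f"{track.add_values[i]:.6f}",
                    "" if rm is None else f"{rm[i]:.6f}",
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "add", "running_median"])
    df.to_csv(out_path, sep="\t", index=False)


def read_add_track(path: str):
    """Read a TSV written by :func:`write_add_track` back into AddTracks."""
    from .add_mapping import AddTrack
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    tracks = []
    for chrom, grp in df.groupby("chrom", sort=False):
        rm = None
        if "running_median" in grp and not grp["running_median"].isna().all():
            rm = grp["running_median"].to_numpy(float)
        tracks.append(
            AddTrack(
                chrom=str(chrom),
                positions=grp["pos"].to_numpy(int),
                add_values=grp["add"].to_numpy(float),
                running_medians=rm,
            )
        )
    return tracks


def write_regions(regions, out_path: str) -> None:
    """Write called linked regions as TSV (chrom, start, end, n_snps, median_add)."""
    rows = [
        (r.chrom, r.start, r.end, r.n_snps, f"{r.median_add:.6f}")
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "median_add"]
    ).to_csv(out_path, sep="\t", index=False)


def read_regions(path: str):
    from .add_mapping import LinkedRegion

    df = pd.read_csv(path, sep="\t")
    return [
        LinkedRegion(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            n_snps=int(row.n_snps),
            median_add=float(row.median_add),
        )
        for row in df.itertuples()
    ]


def write_cascade_report(report, out_path: str) -> None:
    rows = [
        (lv.name, lv.allele_count, "" if lv.gene_count is None else lv.gene_count)
        for lv in report.levels
    ]
    pd.DataFrame(rows, columns=["level", "allele_count", "gene_count"]).to_csv(
        out_path, sep="\t", index=False
    )


def write_candidates(report, out_path: str) -> None:
    from .effects import protein_change_string

    rows = []
    for cand in report.candidates:
        effect = cand.effect
        change = ""
        if effect.protein_pos is not None:
            change = protein_change_string(effect)
        rows.append(
            (
                cand.site.chrom,
                cand.site.pos,
                cand.site.ref_allele,
                cand.site.alt_allele,
                cand.gene_id,
                cand.confidence,
                effect.category.value,
                change,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "confidence",
            "effect", "protein_change",
        ],
    ).to_csv(out_path, sep="\t", index=False)


def write_gene_models(genes, out_path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, confidence attribute)."""
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    with open(out_path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            gid = gene.gene_id
            out.write(
                f"{gene.chrom}\tbulkmapper\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gid};confidence={gene.confidence}\n"
            )
            out.write(
                f"{gene.chrom}\tbulkmapper\tmRNA\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gid}.1;Parent={gid}\n"
            )
            for s, e in gene.exons:
                out.write(
                    f"{gene.chrom}\tbulkmapper\texon\t{s}\t{e}\t.\t"
                    f"{gene.strand}\t.\tParent={gid}.1\n"
                )
            cds = gene.cds if gene.strand == "+" else gene.cds[::-1]
            cum = 0
            for s, e in cds:
                phase = (3 - cum % 3) % 3
                out.write(
                    f"{gene.chrom}\tbulkmapper\tCDS\t{s}\t{e}\t.\t"
                    f"{gene.strand}\t{phase}\tParent={gid}.1\n"
                )
                cum += e - s + 1


def write_fasta(genome: Dict[str, str], out_path: str, width: int = 80) -> None:
    """Write a chromosome-name-keyed sequence dict as FASTA."""
    with open(out_path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
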