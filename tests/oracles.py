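"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the running-median
oracle sorts explicit distance lists, the effect oracle rebuilds and
translates entire coding sequences, and the ADD expectation oracle
enumerates binomial outcomes.
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from bulkmapper.model import BulkSite, GeneModel

_SAFE = ["GCT", "GAA", "CTG", "AAG", "GTC", "TTC", "ATC", "CCT", "ACC", "CAG"]
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_running_median(values, k):
    """Nearest-k running median by explicit per-index distance sorting."""
    values = list(values)
    n = len(values)
    out = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (abs(j - i), j))
        window = sorted(values[j] for j in order[: min(k, n)])
        m = len(window)
        if m % 2:
            out.append(window[m // 2])
        else:
            out.append(0.5 * (window[m // 2 - 1] + window[m // 2]))
    return np.array(out)


def exact_mean_add(depth: int, freq: float) -> float:
    """E[|ref - alt| / depth] for alt ~ Binomial(depth, freq), enumerated."""
    from math import comb

    total = 0.0
    for alt in range(depth + 1):
        p = comb(depth, alt) * freq**alt * (1 - freq) ** (depth - alt)
        total += p * abs(depth - 2 * alt) / depth
    return total


# ---------------------------------------------------------------------------
# Random gene fixtures and the full-translation effect oracle


def random_gene(rng: np.random.Generator, chrom: str = "chrT"):
    """A random small gene (either strand, 1-3 exons) plus its genome dict.

    The CDS starts with ATG, ends with TGA and contains no internal stops;
    exon boundaries may split codons.  Returns (gene, genome, cds_positions)
    where cds_positions lists genomic CDS coordinates in transcript order.
    """
    n_codons = int(rng.integers(10, 40))
    cds_seq = "ATG" + "".join(
        _SAFE[i] for i in rng.integers(0, len(_SAFE), n_codons - 2)
    ) + "TGA"
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, len(cds_seq)), size=n_exons - 1,
                             replace=False).tolist())
    pieces = [cds_seq[a:b] for a, b in zip([0] + cuts, cuts + [len(cds_seq)])]
    utr5 = int(rng.integers(4, 12))
    utr3 = int(rng.integers(4, 12))
    introns = [int(rng.integers(8, 30)) for _ in range(n_exons - 1)]

    bases = "ACGT"
    layout = []  # transcript-oriented: (kind, seq)
    layout.append(("utr", "".join(bases[i] for i in rng.integers(0, 4, utr5))))
    for i, piece in enumerate(pieces):
        layout.append(("cds", piece))
        if i < len(introns):
            layout.append(
                ("intron", "".join(bases[j] for j in rng.integers(0, 4, introns[i])))
            )
    layout.append(("utr", "".join(bases[i] for i in rng.integers(0, 4, utr3))))
    region = "".join(seq for _, seq in layout)

    # transcript-oriented coordinates within the region (0-based)
    cds_intervals_t = []
    exon_intervals_t = []
    offset = 0
    exon_start = 0
    for kind, seq in layout:
        if kind == "intron":
            exon_intervals_t.append((exon_start, offset - 1))
            exon_start = offset + len(seq)
        if kind == "cds":
            cds_intervals_t.append((offset, offset + len(seq) - 1))
        offset += len(seq)
    exon_intervals_t.append((exon_start, offset - 1))

    strand = "+" if rng.integers(0, 2) else "-"
    flank = int(rng.integers(20, 60))
    region_len = len(region)
    if strand == "+":
        genome_region = region
        to_genomic = lambda t: flank + t + 1  # 1-based
    else:
        genome_region = revcomp(region)
        to_genomic = lambda t: flank + (region_len - 1 - t) + 1
    left = "".join(bases[i] for i in rng.integers(0, 4, flank))
    right = "".join(bases[i] for i in rng.integers(0, 4, flank))
    genome = {chrom: left + genome_region + right}

    def iv(t_interval):
        a, b = sorted((to_genomic(t_interval[0]), to_genomic(t_interval[1])))
        return (a, b)

    exons = tuple(sorted(iv(e) for e in exon_intervals_t))
    cds = tuple(sorted(iv(c) for c in cds_intervals_t))
    gene = GeneModel(
        gene_id="rand", chrom=chrom, strand=strand, exons=exons, cds=cds
    )
    cds_positions = [to_genomic(t) for ci in cds_intervals_t
                     for t in range(ci[0], ci[1] + 1)]
    return gene, genome, cds_positions


def oracle_classify_snv(site: BulkSite, gene: GeneModel, genome,
                        cds_positions):
    """Full-translation diff for a coding SNV: rebuild both complete CDS
    sequences, translate them entirely, and locate the residue change.

    Returns (category, protein_pos, ref_aa, alt_aa).
    """
    chrom_seq = genome[gene.chrom]
    ref_cds = []
    for p in cds_positions:
        base = chrom_seq[p - 1].upper()
        ref_cds.append(base.translate(_COMP) if gene.strand == "-" else base)
    idx = cds_positions.index(site.pos)
    alt_base = (site.alt_allele.translate(_COMP)
                if gene.strand == "-" else site.alt_allele)
    alt_cds = ref_cds.copy()
    alt_cds[idx] = alt_base
    ref_prot = str(Seq("".join(ref_cds)).translate())
    alt_prot = str(Seq("".join(alt_cds)).translate())
    if ref_prot == alt_prot:
        return ("synonymous", idx // 3 + 1, ref_prot[idx // 3], alt_prot[idx // 3])
    diff = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    i = diff[0]
    ref_aa, alt_aa = ref_prot[i], alt_prot[i]
    if i == 0 and "".join(ref_cds[:3]) == "ATG":
        cat = "start_loss"
    elif alt_aa == "*":
        cat = "nonsense"
    elif ref_aa == "*":
        cat = "stop_loss"
    else:
        cat = "missense"
    return (cat, i + 1, ref_aa, alt_aa)
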