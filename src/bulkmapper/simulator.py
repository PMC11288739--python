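"""Forward simulator of the bulked-segregant F2 design.

The simulated experiment: a recessive-lethal mutant (kept as a
heterozygous stock) is crossed to a polymorphic cultivar; heterozygous F1
plants are selfed; homozygous-mutant F2 seedlings (identifiable by
phenotype, here by genotype at the causal locus — equivalent for a fully
penetrant recessive) are pooled and sequenced as one bulk.  Two such
mutants induced in the same parent serve as each other's control bulk.

Meiosis follows the Haldane model: each gamete carries a Poisson number
of crossovers with mean equal to the chromosome's genetic map length (in
Morgans), positions drawn from a piecewise-constant recombination
intensity (uniform by default; a near-zero central interval emulates a
pericentromeric recombination coldspot).  Pooled sequencing is modeled as
Poisson depth per marker (conditioned >= 1 so every marker is observable)
with binomially sampled allele reads, optionally perturbed by a
symmetric per-read error rate.

The mutant-parent allele is always written as the VCF ALT allele, so
"fixed for the mutant-parent allele" is directly visible as alt fraction 1.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import BulkSite, GeneModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: codons free of stop codons, used as neutral filler in designed genes
_SAFE_CODONS = (
    "GCT", "GCC", "GAA", "GAG", "CTG", "CTT", "AAA", "AAG",
    "GTC", "GAC", "TTC", "ATC", "CCT", "ACC", "CAG", "CGT",
)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class RecombIntensity:
    """Piecewise-constant crossover intensity over one chromosome.

    ``breaks`` are ascending bp positions from 0 to the chromosome length;
    ``weights`` are relative rates per interval (normalized internally so
    the density integrates to 1).
    """

    breaks: Tuple[float, ...]
    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.weights) + 1:
            raise ValueError("need len(breaks) == len(weights) + 1")
        if any(nxt <= prev for prev, nxt in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")
        if any(w < 0 for w in self.weights) or not any(
            w > 0 for w in self.weights
        ):
            raise ValueError("weights must be non-negative with positive total")

    def cdf(self, x) -> np.ndarray:
        """Normalized integral of the intensity from 0 to x."""
        b = np.asarray(self.breaks, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        seg = np.diff(b) * w
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        x = np.asarray(x, dtype=float)
        i = np.clip(np.searchsorted(b, x, side="right") - 1, 0, len(w) - 1)
        val = cum[i] + (x - b[i]) * w[i]
        return val / cum[-1]


def uniform_intensity(length_bp: int) -> RecombIntensity:
    return RecombIntensity(breaks=(0.0, float(length_bp)), weights=(1.0,))


def coldspot_intensity(
    length_bp: int, cold_start: int, cold_end: int, cold_weight: float = 1e-3
) -> RecombIntensity:
    """Uniform intensity with a near-zero central interval (centromere model)."""
    if not 0 < cold_start < cold_end < length_bp:
        raise ValueError("coldspot must lie strictly inside the chromosome")
    return RecombIntensity(
        breaks=(0.0, float(cold_start), float(cold_end), float(length_bp)),
        weights=(1.0, cold_weight, 1.0),
    )


@dataclass(frozen=True)
class ChromosomeConfig:
    name: str
    length_bp: int
    n_markers: int
    map_length_morgans: float
    intensity: Optional[RecombIntensity] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1 or self.n_markers < 1:
            raise ValueError("length_bp and n_markers must be positive")
        if self.map_length_morgans < 0:
            raise ValueError("map length must be non-negative")

    @property
    def effective_intensity(self) -> RecombIntensity:
        return self.intensity or uniform_intensity(self.length_bp)


@dataclass(frozen=True)
class CausalSpec:
    chrom: str
    pos: int
    gene_id: str
    effect_template: str  # nonsense | missense | frameshift

    def __post_init__(self) -> None:
        if self.effect_template not in ("nonsense", "missense", "frameshift"):
            raise ValueError(
                f"effect_template must be nonsense, missense or frameshift, "
                f"got {self.effect_template!r}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic F2 bulk experiment.

    Defaults mirror the emulated study design: 200 pooled homozygous-mutant
    seedlings sequenced to a mean depth of 20x, error-free reads.
    """

    chromosomes: Tuple[ChromosomeConfig, ...]
    causal: CausalSpec
    bulk_name: str = "mutant"
    n_mutant_pool: int = 200
    n_wildtype_pool: int = 0
    mean_depth: float = 20.0
    error_rate: float = 0.0
    n_decoys: int = 0
    seed: int = 0
    max_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.causal.chrom not in names:
            raise ValueError(
                f"causal chromosome {self.causal.chrom!r} not configured"
            )
        chrom = self.chromosome(self.causal.chrom)
        if not 1 <= self.causal.pos <= chrom.length_bp:
            raise ValueError("causal position outside chromosome")
        if self.n_mutant_pool < 1 or self.n_wildtype_pool < 0:
            raise ValueError("invalid pool sizes")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")

    def chromosome(self, name: str) -> ChromosomeConfig:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def individual_cap(self) -> int:
        if self.max_individuals is not None:
            return self.max_individuals
        return 100 * (self.n_mutant_pool + self.n_wildtype_pool) + 1000


@dataclass(frozen=True)
class PoolFrequencies:
    """Per-marker mutant-parent allele frequency of one pooled bulk."""

    freqs: Dict[str, np.ndarray]
    n_haplotypes: int


@dataclass
class SimResult:
    config: SimConfig
    markers: Dict[str, np.ndarray]
    genetic_positions: Dict[str, np.ndarray]
    mutant_haplotypes: Dict[str, np.ndarray]  # (2 * n_mutant_pool, n_markers)
    wildtype_haplotypes: Optional[Dict[str, np.ndarray]]
    n_simulated: int

    def mutant_pool_frequencies(self) -> PoolFrequencies:
        return PoolFrequencies(
            freqs={
                c: h.mean(axis=0) for c, h in self.mutant_haplotypes.items()
            },
            n_haplotypes=2 * self.config.n_mutant_pool,
        )

    def wildtype_pool_frequencies(self) -> PoolFrequencies:
        if self.wildtype_haplotypes is None:
            raise ValueError("no wild-type pool was simulated")
        return PoolFrequencies(
            freqs={
                c: h.mean(axis=0) for c, h in self.wildtype_haplotypes.items()
            },
            n_haplotypes=2 * self.config.n_wildtype_pool,
        )


# ---------------------------------------------------------------------------
# Markers and meiosis


def draw_marker_positions(
    rng: np.random.Generator, length_bp: int, n: int
) -> np.ndarray:
    """n sorted unique 1-based positions on a chromosome."""
    if n > length_bp:
        raise ValueError("more markers than base pairs")
    unique = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.3) + 16))
    while len(unique) < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        unique = np.unique(np.concatenate([unique, extra]))
    take = np.sort(rng.choice(len(unique), size=n, replace=False))
    return unique[take]


def default_markers(
    config: SimConfig, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Marker panel per chromosome, with the causal position inserted."""
    markers = {
        c.name: draw_marker_positions(rng, c.length_bp, c.n_markers)
        for c in config.chromosomes
    }
    cm = markers[config.causal.chrom]
    if config.causal.pos not in cm:
        markers[config.causal.chrom] = np.sort(
            np.append(cm, config.causal.pos)
        )
    return markers


def sample_gametes(
    rng: np.random.Generator,
    n: int,
    genetic_positions: Dict[str, np.ndarray],
    map_lengths: Dict[str, float],
) -> Dict[str, np.ndarray]:
    """Simulate n recombinant F1 gametes (Haldane: Poisson crossovers, no
    interference).  Returns per-chromosome (n, n_markers) arrays of parental
    origin: 1 = mutant parent, 0 = cultivar parent."""
    out = {}
    for chrom, gpos in genetic_positions.items():
        length = map_lengths[chrom]
        haps = np.empty((n, len(gpos)), dtype=np.int8)
        phases = rng.integers(0, 2, size=n)
        n_crossovers = rng.poisson(length, size=n) if length > 0 else np.zeros(n, int)
        for i in range(n):
            if n_crossovers[i] == 0:
                haps[i, :] = phases[i]
            else:
                crossovers = np.sort(rng.uniform(0.0, length, n_crossovers[i]))
                haps[i, :] = (
                    phases[i] + np.searchsorted(crossovers, gpos)
                ) % 2
        out[chrom] = haps
    return out


def simulate_f2(
    config: SimConfig,
    markers: Optional[Dict[str, np.ndarray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimResult:
    """Simulate F2 individuals and select the phenotyped pools.

    The mutant pool comprises the first ``n_mutant_pool`` individuals
    homozygous for the mutant-parent allele at the causal marker; the
    wild-type pool (if requested) the first ``n_wildtype_pool`` that are
    not.  Raises when the cap on simulated individuals is hit first.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if markers is None:
        markers = default_markers(config, rng)
    causal_chrom = config.causal.chrom
    if config.causal.pos not in markers[causal_chrom]:
        raise ValueError("causal position must coincide with a marker")
    causal_idx = int(np.searchsorted(markers[causal_chrom], config.causal.pos))

    genetic_positions = {}
    map_lengths = {}
    for c in config.chromosomes:
        gpos = c.map_length_morgans * c.effective_intensity.cdf(markers[c.name])
        genetic_positions[c.name] = gpos
        map_lengths[c.name] = c.map_length_morgans

    mutant_rows: Dict[str, List[np.ndarray]] = {c.name: [] for c in config.chromosomes}
    wildtype_rows: Dict[str, List[np.ndarray]] = {c.name: [] for c in config.chromosomes}
    n_mut = n_wt = n_simulated = 0
    cap = config.individual_cap
    while n_mut < config.n_mutant_pool or n_wt < config.n_wildtype_pool:
        if n_simulated >= cap:
            raise RuntimeError(
                f"could not assemble pools within {cap} simulated F2 "
                f"individuals; increase max_individuals"
            )
        remaining = max(
            config.n_mutant_pool - n_mut, (config.n_wildtype_pool - n_wt) // 3 + 1
        )
        batch = min(max(64, int(4.4 * remaining)), cap - n_simulated)
        gametes = sample_gametes(rng, 2 * batch, genetic_positions, map_lengths)
        causal_h = gametes[causal_chrom][:, causal_idx]
        is_mutant = (causal_h[0::2] == 1) & (causal_h[1::2] == 1)
        n_simulated += batch
        for ind in range(batch):
            if is_mutant[ind] and n_mut < config.n_mutant_pool:
                for chrom in mutant_rows:
                    mutant_rows[chrom].append(gametes[chrom][2 * ind])
                    mutant_rows[chrom].append(gametes[chrom][2 * ind + 1])
                n_mut += 1
            elif not is_mutant[ind] and n_wt < config.n_wildtype_pool:
                for chrom in wildtype_rows:
                    wildtype_rows[chrom].append(gametes[chrom][2 * ind])
                    wildtype_rows[chrom].append(gametes[chrom][2 * ind + 1])
                n_wt += 1

    mutant_haps = {c: np.array(rows, dtype=np.int8) for c, rows in mutant_rows.items()}
    wildtype_haps = None
    if config.n_wildtype_pool > 0:
        wildtype_haps = {
            c: np.array(rows, dtype=np.int8) for c, rows in wildtype_rows.items()
        }
    return SimResult(
        config=config,
        markers=markers,
        genetic_positions=genetic_positions,
        mutant_haplotypes=mutant_haps,
        wildtype_haplotypes=wildtype_haps,
        n_simulated=n_simulated,
    )


# ---------------------------------------------------------------------------
# Pooled read sampling


def _positive_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    depth = rng.poisson(mean, size)
    zero = depth == 0
    while zero.any():
        depth[zero] = rng.poisson(mean, int(zero.sum()))
        zero = depth == 0
    return depth


def sample_pool_reads(
    freqs: PoolFrequencies,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Sample pooled reads at every marker for one bulk.

    Depth ~ Poisson(mean_depth) conditioned >= 1; mutant-parent (alt) reads
    ~ Binomial(depth, f (1 - e) + (1 - f) e).  Returns per-chromosome
    (ref_reads, alt_reads) arrays.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    e = config.error_rate
    out = {}
    for chrom, f in freqs.freqs.items():
        depth = _positive_poisson(rng, config.mean_depth, len(f))
        p = f * (1.0 - e) + (1.0 - f) * e
        alt = rng.binomial(depth, p)
        out[chrom] = (depth - alt, alt)
    return out


# ---------------------------------------------------------------------------
# Designed genes for the synthetic fixture


@dataclass(frozen=True)
class DesignedVariant:
    """A planted variant together with the gene designed around it."""

    gene: Optional[GeneModel]
    segments: Tuple[Tuple[int, str], ...]  # (genomic start, sequence) to paste
    pos: int
    ref: str
    alt: str
    expected_category: str
    protein_change: str


def _random_codons(rng: np.random.Generator, n: int) -> List[str]:
    return [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def design_causal_gene(
    chrom: str,
    causal_pos: int,
    gene_id: str,
    template: str,
    rng: np.random.Generator,
    n_codons: int = 377,
    utr_len: int = 30,
    intron_len: int = 150,
) -> DesignedVariant:
    """Design a two-exon HC gene whose CDS carries the template mutation at
    ``causal_pos``.

    Templates: nonsense plants TGG->TGA at residue 291 (rendered W291*),
    missense plants TCC->TTC at residue 212 (S212F), frameshift a 1 bp
    deletion at residue 340.
    """
    codons = ["ATG"] + _random_codons(rng, n_codons - 2) + ["TGA"]
    if template == "nonsense":
        residue = min(291, n_codons - 2)
        codons[residue - 1] = "TGG"
        t_index, ref_t, alt_t = 3 * (residue - 1) + 2, "G", "A"
        expected, change = "nonsense", f"W{residue}*"
    elif template == "missense":
        residue = min(212, n_codons - 2)
        codons[residue - 1] = "TCC"
        t_index, ref_t, alt_t = 3 * (residue - 1) + 1, "C", "T"
        expected, change = "missense", f"S{residue}F"
    elif template == "frameshift":
        residue = min(340, n_codons - 2)
        t_index, ref_t, alt_t = 3 * (residue - 1), None, None
        expected, change = "frameshift", ""
    else:
        raise ValueError(f"unknown template {template!r}")

    cds_seq = "".join(codons)
    split = (n_codons // 2) * 3  # CDS bases in exon 1 (codon boundary)
    if not t_index >= split:
        raise ValueError("template residue must sit in the second exon")

    # transcript index -> genomic offset from gene start (plus strand)
    def genomic_offset(t: int) -> int:
        if t < split:
            return utr_len + t
        return utr_len + split + intron_len + (t - split)

    gene_start = causal_pos - genomic_offset(t_index)
    if gene_start < 1:
        raise ValueError("causal position too close to the chromosome start")
    utr5 = _random_seq(rng, utr_len)
    intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"
    utr3 = _random_seq(rng, utr_len)
    full = utr5 + cds_seq[:split] + intron + cds_seq[split:] + utr3

    exon1 = (gene_start, gene_start + utr_len + split - 1)
    exon2_start = exon1[1] + intron_len + 1
    exon2 = (exon2_start, exon2_start + (len(cds_seq) - split) + utr_len - 1)
    cds1 = (gene_start + utr_len, exon1[1])
    cds2 = (exon2_start, exon2_start + (len(cds_seq) - split) - 1)
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=((exon1), (exon2)),
        cds=((cds1), (cds2)),
        confidence="HC",
    )

    if template == "frameshift":
        ref = cds_seq[t_index : t_index + 2]
        alt = cds_seq[t_index]
    else:
        assert cds_seq[t_index] == ref_t
        ref, alt = ref_t, alt_t
    return DesignedVariant(
        gene=gene,
        segments=((gene_start, full),),
        pos=causal_pos,
        ref=ref,
        alt=alt,
        expected_category=expected,
        protein_change=change,
    )


def design_decoy_gene(
    chrom: str,
    var_pos: int,
    gene_id: str,
    kind: str,
    rng: np.random.Generator,
    n_codons: int = 30,
    utr_len: int = 20,
    intron_len: int = 120,
) -> DesignedVariant:
    """Small single-variant decoy genes.

    Kinds: "synonymous" (HC gene, CTC->CTT Leu), "lc_missense" (LC gene,
    GCT->GAT Ala->Asp) and "intronic" (HC gene, substitution mid-intron).
    """
    codons = ["ATG"] + _random_codons(rng, n_codons - 2) + ["TGA"]
    residue = n_codons // 2
    if kind == "synonymous":
        codons[residue - 1] = "CTC"
        t_index, ref, alt = 3 * (residue - 1) + 2, "C", "T"
        expected, confidence, change = "synonymous", "HC", ""
        with_intron = False
    elif kind == "lc_missense":
        codons[residue - 1] = "GCT"
        t_index, ref, alt = 3 * (residue - 1) + 1, "C", "A"
        expected, confidence, change = "missense", "LC", f"A{residue}D"
        with_intron = True  # variant still exonic; intron adds structure
    elif kind == "intronic":
        t_index, ref, alt = None, None, None
        expected, confidence, change = "intronic", "HC", ""
        with_intron = True
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")

    cds_seq = "".join(codons)
    split = (n_codons // 2 + 2) * 3 if with_intron else len(cds_seq)
    if with_intron and t_index is not None and t_index >= split:
        split = len(cds_seq)  # keep the variant in exon 1 for simplicity
        with_intron = False
    eff_intron = intron_len if with_intron and split < len(cds_seq) else 0

    if kind == "intronic":
        offset = utr_len + split + eff_intron // 2
    else:
        offset = utr_len + t_index  # all planted exonic variants sit in exon 1
    gene_start = var_pos - offset
    if gene_start < 1:
        raise ValueError("variant too close to the chromosome start")

    utr5 = _random_seq(rng, utr_len)
    intron = (
        "GT" + _random_seq(rng, eff_intron - 4) + "AG" if eff_intron else ""
    )
    utr3 = _random_seq(rng, utr_len)
    full = utr5 + cds_seq[:split] + intron + cds_seq[split:] + utr3

    exons = []
    cds = []
    exon1_end = gene_start + utr_len + split - 1
    if eff_intron:
        exon2_start = exon1_end + eff_intron + 1
        exons = [
            (gene_start, exon1_end),
            (exon2_start, exon2_start + (len(cds_seq) - split) + utr_len - 1),
        ]
        cds = [
            (gene_start + utr_len, exon1_end),
            (exon2_start, exon2_start + (len(cds_seq) - split) - 1),
        ]
    else:
        exons = [(gene_start, exon1_end + utr_len)]
        cds = [(gene_start + utr_len, gene_start + utr_len + len(cds_seq) - 1)]
    gene = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=tuple(exons),
        cds=tuple(cds),
        confidence=confidence,
    )
    if kind == "intronic":
        intron_pos_in_full = offset  # 0-based within `full`
        ref = full[intron_pos_in_full]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    else:
        assert cds_seq[t_index] == ref
    return DesignedVariant(
        gene=gene,
        segments=((gene_start, full),),
        pos=var_pos,
        ref=ref,
        alt=alt,
        expected_category=expected,
        protein_change=change,
    )


# ---------------------------------------------------------------------------
# Two-bulk synthetic fixture


_DECOY_KINDS = ("intergenic", "synonymous", "intronic", "lc_missense")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _reserve(occupied: List[Tuple[int, int]], start: int, end: int) -> bool:
    for s, e in occupied:
        if start <= e and s <= end:
            return False
    occupied.append((start, end))
    return True


def _place_variant(
    rng: np.random.Generator,
    chrom_cfg: ChromosomeConfig,
    occupied: List[Tuple[int, int]],
    forbidden: set,
    reserve_before: int,
    reserve_after: int,
    near: Optional[int] = None,
    near_band: Tuple[int, int] = (2000, 12000),
) -> int:
    lo = reserve_before + 1
    hi = chrom_cfg.length_bp - reserve_after - 1
    for _ in range(500):
        if near is not None:
            offset = int(rng.integers(*near_band))
            pos = near + (offset if rng.integers(0, 2) else -offset)
        else:
            pos = int(rng.integers(lo, hi))
        if not lo <= pos <= hi or pos in forbidden:
            continue
        start, end = pos - reserve_before, pos + reserve_after
        trial = occupied.copy()
        if _reserve(trial, start, end):
            occupied.append((start, end))
            forbidden.add(pos)
            return pos
    raise RuntimeError(
        f"could not place a variant on {chrom_cfg.name}; chromosome too crowded"
    )


def make_fixture(config_a: SimConfig, config_b: SimConfig, out_dir: str) -> dict:
    """Write a complete two-bulk synthetic dataset: VCF + GFF3 + FASTA + truth.

    The two configs share one marker panel (the cultivar-cross
    polymorphisms) and must place their causal loci on different
    chromosomes.  Each bulk additionally carries its private planted causal
    variant and ``n_decoys`` private decoy variants (cycling through
    intergenic, synonymous, intronic and LC-gene missense kinds, the first
    few placed inside the expected linked region).

    Returns a dict with keys vcf, gff, fasta, truth, bulk_names.
    """
    from . import variant_io

    if config_a.causal.chrom == config_b.causal.chrom:
        raise ValueError("causal chromosomes of the two bulks must differ")
    if config_a.chromosomes != config_b.chromosomes:
        raise ValueError("the two configs must share the same chromosome panel")
    if config_a.bulk_name == config_b.bulk_name:
        raise ValueError("bulk names must differ")
    os.makedirs(out_dir, exist_ok=True)

    seed_seq = np.random.SeedSequence(
        [config_a.seed & 0x7FFFFFFF, config_b.seed & 0x7FFFFFFF]
    )
    (rng_panel, rng_genome, rng_genes, rng_sim_a, rng_sim_b,
     rng_reads_a, rng_reads_b, rng_priv) = [
        np.random.default_rng(s) for s in seed_seq.spawn(8)
    ]

    chrom_cfgs = {c.name: c for c in config_a.chromosomes}
    chrom_order = [c.name for c in config_a.chromosomes]

    # shared marker panel, both causal positions inserted as loci
    markers = {
        c.name: draw_marker_positions(rng_panel, c.length_bp, c.n_markers)
        for c in config_a.chromosomes
    }
    for causal in (config_a.causal, config_b.causal):
        arr = markers[causal.chrom]
        if causal.pos not in arr:
            markers[causal.chrom] = np.sort(np.append(arr, causal.pos))
    marker_sets = {c: set(int(p) for p in m) for c, m in markers.items()}

    # reference genome as mutable byte arrays
    genome_arrays = {
        c.name: _BASES[rng_genome.integers(0, 4, c.length_bp)].copy()
        for c in config_a.chromosomes
    }

    def paste(chrom: str, start: int, seq: str) -> None:
        arr = genome_arrays[chrom]
        frag = np.frombuffer(seq.encode(), dtype="S1")
        arr[start - 1 : start - 1 + len(frag)] = frag

    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_order}
    forbidden: Dict[str, set] = {
        c: set(marker_sets[c]) for c in chrom_order
    }
    genes: List[GeneModel] = []
    truth_rows: List[tuple] = []
    private: Dict[str, List[Tuple[str, str, DesignedVariant]]] = {}

    for config in (config_a, config_b):
        planted: List[Tuple[str, str, DesignedVariant]] = []
        causal = config.causal
        dv = design_causal_gene(
            causal.chrom, causal.pos, causal.gene_id, causal.effect_template,
            rng_genes,
        )
        if not _reserve(
            occupied[causal.chrom], dv.gene.start - 50, dv.gene.end + 50
        ):
            raise RuntimeError("causal gene placement collision")
        paste(causal.chrom, dv.segments[0][0], dv.segments[0][1])
        genes.append(dv.gene)
        planted.append(("causal", causal.chrom, dv))

        n_region = min(8, config.n_decoys)
        other_chroms = [c for c in chrom_order]
        for i in range(config.n_decoys):
            kind = _DECOY_KINDS[i % len(_DECOY_KINDS)]
            if i < n_region:
                chrom = causal.chrom
                near = causal.pos
            else:
                chrom = other_chroms[i % len(other_chroms)]
                near = None
            cfg = chrom_cfgs[chrom]
            if kind == "intergenic":
                pos = _place_variant(
                    rng_priv, cfg, occupied[chrom], forbidden[chrom],
                    10, 10, near=near,
                )
                ref = genome_arrays[chrom][pos - 1].decode()
                dvd = DesignedVariant(
                    gene=None, segments=(), pos=pos, ref=ref,
                    alt=_other_base(rng_priv, ref),
                    expected_category="intergenic", protein_change="",
                )
            else:
                pos = _place_variant(
                    rng_priv, cfg, occupied[chrom], forbidden[chrom],
                    300, 300, near=near,
                )
                gene_id = f"{config.bulk_name}_decoy_{i:02d}"
                dvd = design_decoy_gene(chrom, pos, gene_id, kind, rng_priv)
                paste(chrom, dvd.segments[0][0], dvd.segments[0][1])
                genes.append(dvd.gene)
            planted.append(("decoy", chrom, dvd))
            truth_rows.append(
                (
                    config.bulk_name, chrom, dvd.pos, dvd.ref, dvd.alt,
                    "decoy", dvd.gene.gene_id if dvd.gene else "",
                    dvd.expected_category, dvd.protein_change,
                )
            )
        truth_rows.append(
            (
                config.bulk_name, causal.chrom, dv.pos, dv.ref, dv.alt,
                "causal", causal.gene_id, dv.expected_category,
                dv.protein_change,
            )
        )
        private[config.bulk_name] = planted

    # simulate both pools over the shared panel and sample their reads
    res_a = simulate_f2(config_a, markers=markers, rng=rng_sim_a)
    res_b = simulate_f2(config_b, markers=markers, rng=rng_sim_b)
    reads_a = sample_pool_reads(res_a.mutant_pool_frequencies(), config_a, rng_reads_a)
    reads_b = sample_pool_reads(res_b.mutant_pool_frequencies(), config_b, rng_reads_b)

    name_a, name_b = config_a.bulk_name, config_b.bulk_name
    causal_pos = {
        name_a: (config_a.causal.chrom, config_a.causal.pos),
        name_b: (config_b.causal.chrom, config_b.causal.pos),
    }

    def private_counts(
        target_config: SimConfig, other_config: SimConfig
    ) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """(target, other) AD pairs for a variant private to target (f=1 vs 0)."""
        dt = int(_positive_poisson(rng_priv, target_config.mean_depth, 1)[0])
        alt_t = int(rng_priv.binomial(dt, 1.0 - target_config.error_rate))
        do = int(_positive_poisson(rng_priv, other_config.mean_depth, 1)[0])
        alt_o = int(rng_priv.binomial(do, other_config.error_rate))
        return (dt - alt_t, alt_t), (do - alt_o, alt_o)

    sites: List[BulkSite] = []
    for chrom in chrom_order:
        positions = markers[chrom]
        for i, pos in enumerate(positions):
            pos = int(pos)
            if (chrom, pos) == causal_pos[name_a] or (chrom, pos) == causal_pos[name_b]:
                continue  # causal loci written as private records below
            ref = genome_arrays[chrom][pos - 1].decode()
            alt = _other_base(rng_priv, ref)
            sites.append(
                BulkSite(
                    chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                    counts={
                        name_a: (int(reads_a[chrom][0][i]), int(reads_a[chrom][1][i])),
                        name_b: (int(reads_b[chrom][0][i]), int(reads_b[chrom][1][i])),
                    },
                )
            )
    for bulk_name, planted in private.items():
        target_config = config_a if bulk_name == name_a else config_b
        other_config = config_b if bulk_name == name_a else config_a
        other_name = other_config.bulk_name
        for kind, chrom, dvd in planted:
            if kind == "causal":
                # read depth at the causal locus comes from the simulated pool
                idx = int(np.searchsorted(markers[chrom], dvd.pos))
                target_counts = (
                    int((reads_a if bulk_name == name_a else reads_b)[chrom][0][idx]),
                    int((reads_a if bulk_name == name_a else reads_b)[chrom][1][idx]),
                )
                do = int(_positive_poisson(rng_priv, other_config.mean_depth, 1)[0])
                alt_o = int(rng_priv.binomial(do, other_config.error_rate))
                other_counts = (do - alt_o, alt_o)
            else:
                target_counts, other_counts = private_counts(
                    target_config, other_config
                )
            sites.append(
                BulkSite(
                    chrom=chrom, pos=dvd.pos, ref_allele=dvd.ref,
                    alt_allele=dvd.alt,
                    counts={bulk_name: target_counts, other_name: other_counts},
                )
            )
    rank = {c: i for i, c in enumerate(chrom_order)}
    sites.sort(key=lambda s: (rank[s.chrom], s.pos))

    paths = {
        "vcf": os.path.join(out_dir, "bulks.vcf"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "fasta": os.path.join(out_dir, "genome.fa"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    contigs = [(c.name, c.length_bp) for c in config_a.chromosomes]
    variant_io.write_biallelic_sites(sites, (name_a, name_b), contigs, paths["vcf"])
    variant_io.write_gene_models(genes, paths["gff"])
    genome = {c: genome_arrays[c].tobytes().decode() for c in chrom_order}
    variant_io.write_fasta(genome, paths["fasta"])

    import pandas as pd

    pd.DataFrame(
        truth_rows,
        columns=[
            "bulk", "chrom", "pos", "ref", "alt", "kind", "gene_id",
            "expected_effect", "protein_change",
        ],
    ).sort_values(["bulk", "chrom", "pos"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    paths["bulk_names"] = (name_a, name_b)
    return paths
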