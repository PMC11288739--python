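# bulkmapper

Bulked-segregant mapping of induced mutations from pooled F2 allele
depths — with a forward F2 simulator for end-to-end validation.

## The problem

Identifying the causal gene behind an induced mutant phenotype in a
large-genome crop (the motivating case is barley, *Hordeum vulgare*)
is classically done by bulked segregant analysis (BSA): cross the mutant
to a polymorphic cultivar, self the heterozygous F1, pool F2 seedlings by
phenotype, and sequence the pools.  For a recessive lethal, the mutant
pool is homozygous for the mutant-parent haplotype around the causal
locus, so nearby markers are fixed for the mutant-parent allele, while
unlinked markers segregate ~1:1 in reads.  When two mutants induced in
the *same* parent cultivar are mapped simultaneously, each mutant bulk
doubles as the other's control — no wild-type pool needs sequencing,
halving cost.

`bulkmapper` implements the analysis downstream of variant calling:

1. **ADD mapping.**  For each biallelic SNP with ref/alt read counts
   $(r, a)$ in one pool, the allele depth difference is

   $$\mathrm{ADD} = \frac{|r - a|}{r + a} \in [0, 1],$$

   1 meaning the pool's reads are fixed for one allele (complete
   linkage).  Sites are filtered by depth (within 1 SD of the mean
   depth) and by the control bulk's ADD (> 0.3 flags non-Mendelian
   artifacts), then smoothed per chromosome with a running median over
   the nearest *k* SNPs; maximal runs of smoothed values ≥ 0.995 are
   called as linked regions.
2. **Candidate cascade.**  Variants are narrowed in seven levels:
   unique to the target bulk (zero alt support in the control) →
   homozygous (alt fraction ≥ 0.9, depth ≥ 5) → on a mapped chromosome →
   inside a linked region → within a gene body → altering the amino acid
   sequence (missense, nonsense, frameshift, start/stop loss, in-frame
   indel) → in a high-confidence (HC) gene.  Counts are reported at every
   level.
3. **Effect classification.**  A minimal desk-scale coding-effect
   classifier (codon translation on either strand from GFF3 gene models
   and the genome FASTA) supplies step 6 and renders changes like
   `S212F` or `W291*`.
4. **F2 forward simulation.**  Haldane-model meiosis (Poisson crossovers,
   piecewise-constant recombination intensity, optional pericentromeric
   coldspot), genotype-based selection of the homozygous-mutant pool, and
   binomial pooled read sampling — emitting complete synthetic
   VCF/GFF3/FASTA fixtures with planted causal mutations, decoys, and a
   truth table.

Inputs are standard formats: a two-sample VCF with per-sample `AD`
fields, a GFF3 with a gene-level `confidence` attribute, and the genome
FASTA.

## Worked example

Simulate a two-mutant dataset (three 2-Mb chromosomes, 4000 markers
each, 200 pooled mutant seedlings per bulk at 20× depth, 25 decoy
variants per bulk), then run the full pipeline in both directions:

```bash
bulkmapper simulate --config sim.yaml --out-dir demo/data
bulkmapper run --vcf demo/data/bulks.vcf --gff demo/data/genes.gff3 \
    --fasta demo/data/genome.fa --bulk-a bulkJ --bulk-b bulkL \
    --window-k 250 --out-dir demo/out
```

with `sim.yaml`:

```yaml
seed: 5
mean_depth: 20
n_mutant_pool: 200
chromosomes:
  - {name: chr1H, length_bp: 2000000, n_markers: 4000, map_length_morgans: 1.2}
  - {name: chr2H, length_bp: 2000000, n_markers: 4000, map_length_morgans: 1.2}
  - {name: chr3H, length_bp: 2000000, n_markers: 4000, map_length_morgans: 1.2}
bulks:
  - name: bulkJ
    causal: {chrom: chr1H, pos: 400000, gene_id: geneJ, effect_template: nonsense}
    n_decoys: 25
  - name: bulkL
    causal: {chrom: chr3H, pos: 1000000, gene_id: geneL, effect_template: missense}
    n_decoys: 25
```

(A chromosome may also declare a recombination coldspot:
`coldspot: {start: 800000, end: 1200000, weight: 0.001}`.)

The run prints

```
bulkJ: 2 region(s); candidates: geneJ:nonsense
bulkL: 2 region(s); candidates: geneL:missense
```

and `demo/out/bulkJ.cascade.tsv` holds the per-level counts:

```
level	allele_count	gene_count
unique_alleles_all	27
homozygous_all	26
homozygous_mapped_chromosome	15
homozygous_mapped_region	10
homozygous_in_genes	8	8
genes_with_aa_change	3	3
hc_genes_with_aa_change	1	1
```

Reading it: of the 27 alleles private to `bulkJ` (its planted causal
variant plus 25 decoys survive the control contrast, the shared
cultivar polymorphisms do not), 26 are homozygous in the pool, 15 lie on
the mapped chromosome, 10 inside the linked region (which spans the
planted position 400 000), 8 fall in gene bodies, 3 change the protein —
and exactly 1 sits in a high-confidence gene: the planted nonsense
mutation, reported in `bulkJ.candidates.tsv` as

```
chrom	pos	ref	alt	gene_id	confidence	effect	protein_change
chr1H	400000	G	A	geneJ	HC	nonsense	W291*
```

The same objects are available as a library
(`bulkmapper.simulate_f2`, `bulkmapper.run_cascade`,
`bulkmapper.pipeline.run_full`, …); `run_summary.json` carries the whole
result with stable key order, so identical seeds reproduce identical
bytes.

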