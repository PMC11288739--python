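# Methods

This note records the model, the numerical choices, and what the
synthetic-data validation does and does not demonstrate.

## Mapping statistic

For a biallelic site with ref/alt read counts $(r, a)$ in one pooled
bulk, the allele depth difference is $\mathrm{ADD} = |r-a|/(r+a)$, which
is undefined at $r=a=0$ (such sites are excluded before computation) and
equals 1 when the pool's reads are fixed for either allele.  In an F2
pool selected for a recessive phenotype, the expectation of the
underlying allele-frequency imbalance is 1 at the causal locus, decays
with genetic distance, and is 0 at unlinked markers; at finite depth
ADD is upward-biased at balanced sites (e.g. its expectation at depth 2
and frequency ½ is 0.5, at depth 4 it is 0.375 — these exact binomial
enumerations anchor the sampling tests), which is why the signal is
thresholded on the *running median*, not on the mean.

### Filters

* **Depth band.**  Sites are retained when their depth lies within
  `depth_sd_multiplier` (default 1.0) standard deviations of the mean
  depth, boundaries inclusive.  The standard deviation uses the
  population formula (divide by *n*); at the site counts involved the
  estimator choice is numerically irrelevant, but one must be fixed for
  reproducibility.  The band is recomputed from whatever collection the
  filter is given, so the operation is not idempotent in the strict
  sense — it is a one-shot preprocessing step, applied once per run.
  Low-depth sites give noisy frequencies; excess-depth sites are
  typically collapsed repeats.
* **Control ADD.**  Sites with ADD > `control_add_max` (default 0.3) in
  the control bulk are removed, the 0.3 boundary itself retained.  In
  the mutual-control design a high control ADD marks a site that is not
  segregating ~1:1 in an unselected background — either an artifact, or
  (at sites near the *control's own* causal locus) a region that the
  other direction of the analysis will map.  Per-bulk application (each
  bulk filtered on its own depth distribution, then on the other bulk's
  ADD) is used throughout.

### Running median and region calling

The smoother replaces each site's ADD with the median over the `window_k`
sites nearest *by index* on the same chromosome ("nearest k SNPs", not
nearest k base pairs).  The nearest-k window is contiguous; for even k
the extra member sits on the lower-index side (ties toward the lower
index), and at chromosome ends the window shifts rather than shrinks, so
it always holds exactly min(k, n) members.  The median of an even count
is the mean of the two middle values.  A brute-force sort-based oracle
verifies the vectorized implementation elementwise on random tracks.

`window_k` defaults to 2500, appropriate for whole-genome tracks of
~1M retained SNPs.  The packaged synthetic panels carry 4000–5000
markers per chromosome, and all packaged tests and the acceptance script
use `window_k = 250`, preserving the window-to-track ratio.  The window
must stay small relative to the marker density per Morgan: with pools of
~200 individuals the fully linked core around the causal locus spans
roughly 1/(2N) Morgan of flanking map per side before the first selected
recombinant, and the window median stays at exactly 1 only while most of
the window lies in the high-frequency neighborhood.  At 20× depth this
requires on the order of `window_k`/2 × depth markers per Morgan
(≳3000/Morgan for k = 250), which the packaged panels satisfy.

Linked regions are maximal runs of consecutive sites with running median
≥ `region_threshold`.  The default 0.995 rather than exactly 1 keeps
isolated error reads from fragmenting a truly fixed region; with
error-free reads the behavior is identical to a threshold of 1, and
setting `region_threshold = 1.0` recovers exact-match semantics.

## Candidate cascade

Seven ordered levels, counts non-increasing by construction:

1. *Unique alleles*: alt allele read-supported in the target bulk with
   zero alt reads at the same (chrom, pos, ref, alt) in the control —
   including sites absent from the control collection.  Because the two
   bulks share the same cross, this removes nearly all natural
   polymorphism and leaves predominantly induced, bulk-private variants.
2. *Homozygous*: read-count homozygosity, alt fraction ≥ 0.9 at depth
   ≥ 5 (both configurable).  A read-count rule is used instead of an
   upstream caller's genotype because the pipeline consumes allele
   depths only; the defaults emulate typical caller behavior at 20×.
3. *Mapped chromosome* and 4. *mapped region*: positional restriction to
   the called linked regions (inclusive boundaries).  If mapping called
   no region, levels 3–7 are empty.
5. *In genes*: position within a gene's outermost span — intronic and
   UTR hits count here, deliberately, since the next level asks the
   protein question.
6. *Amino-acid change*: effects in {missense, nonsense, frameshift,
   start-loss, stop-loss, in-frame indel}.  Splice-region variants (2 bp
   of intron at each junction) are *not* counted: the criterion is an
   altered amino-acid sequence, and splice effects cannot be resolved at
   desk scale.  Start- and stop-loss are included although rarely hit:
   they alter the protein by the same criterion.  The allele count is
   distinct variants; the gene count is distinct genes (a variant in
   overlapping genes counts each once).
7. *HC genes*: restriction to high-confidence gene models; the final
   candidate list reports these variants with their protein change.

ADD mapping uses biallelic SNPs only; the cascade takes all biallelic
variants including anchored indels — a 1 bp deletion causing a
frameshift must be able to reach the final level.

## Effect classifier

Standard genetic code; translation starts at the annotated CDS start;
the stop codon belongs to the CDS, whose total length must be a multiple
of 3 (otherwise the classifier refuses with an explicit error).  An SNV
in the CDS is classified by translating its codon before and after the
substitution (reverse-complementing on the minus strand); codon-split
exon junctions are handled by mapping transcript positions through the
CDS intervals.  Coding indels are frameshift when the inserted-minus-
deleted CDS length is not a multiple of 3, in-frame otherwise; for
indels spanning a CDS boundary only the CDS-overlapping portion counts.
Selenocysteine and alternative codes are unsupported.  Correctness is
checked against an independent oracle that rebuilds both complete CDS
sequences, translates them fully, and diffs the proteins, on hundreds of
random gene fixtures of both strands.

## F2 simulator

* **Meiosis.**  Haldane model: each gamete receives a Poisson-distributed
  crossover count with mean equal to the chromosome's map length in
  Morgans and crossover positions drawn from a piecewise-constant
  intensity (no interference).  Markers are placed uniformly at random;
  their genetic positions are the map length times the intensity CDF.
  The two-marker recombination fraction therefore follows
  $r = (1-e^{-2d})/2$, verified against the closed form.
* **Selection.**  Homozygous-mutant F2 individuals are identified by
  genotype at the causal marker — equivalent to phenotyping for a fully
  penetrant recessive.  The mutant pool takes the first
  `n_mutant_pool` such individuals; an optional non-mutant ("green")
  pool takes individuals that are not homozygous mutant.  A cap on
  simulated individuals turns an unattainable pool into an explicit
  error.
* **Reads.**  Per marker, depth ~ Poisson(`mean_depth`) conditioned ≥ 1
  (so every marker is observable; truly zero-coverage sites are the
  depth filter's concern, not the simulator's), and mutant-parent reads
  ~ Binomial(depth, f(1−e) + (1−f)e) with symmetric error rate e.  The
  mutant-parent allele is always the VCF ALT allele, so fixation is
  directly visible as alt fraction 1.
* **Defaults** follow the emulated experiment: 200 pooled mutant
  seedlings, mean depth 20×, error rate 0.  Map lengths of ~1.2 Morgans
  per chromosome are used in the packaged panels, a realistic cereal
  figure; the centromere scenario suppresses intensity to 10⁻³ of
  baseline over the central 40% of the chromosome.
* **Two-bulk fixture.**  Both bulks share one marker panel (the
  cultivar-cross polymorphisms) simulated independently through each
  bulk's pedigree; each bulk additionally carries its private causal
  variant (nonsense TGG→TGA at residue 291, missense TCC→TTC at residue
  212, or a 1 bp frameshift deletion — planted inside a designed
  two-exon HC gene whose sequence is written into the genome FASTA) and
  private decoys cycling through intergenic, synonymous, intronic and
  LC-gene-missense kinds, the first few placed inside the expected
  linked region.  A truth table lists every planted variant with its
  expected effect.  All randomness flows from the two config seeds, and
  fixture files are byte-identical across reruns.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the statistics, filters, smoother,
cascade and classifier implement their definitions exactly, that the
pipeline recovers a planted recessive mutation as the sole HC candidate
in both directions of the mutual-control design at study-like pool size
and depth, and that a recombination coldspot widens the called region as
expected.  The simulator does not model mapping bias, repeat-induced
depth artifacts, contamination, caller-specific genotype errors, or
structural variants, so passing tests bound correctness of the
*analysis*, not the difficulty of real whole-genome data; absolute
variant counts at the cascade levels depend entirely on the real
mutational load and polymorphism density and are not reproduced at
fixture scale.

## Problem sizes in packaged runs

Chosen for single-CPU desk-scale runs; all are ordinary parameters of
the public API:

* Mapping acceptance checks: 5000 markers/chromosome (7 chromosomes for
  the genome-wide check, 1 for the coldspot), pool 200, depth 20,
  `window_k` 250.
* Coldspot pairing: 20 paired seeded replicates at 3000 markers, pool
  100.
* Mutual-control fixture: 3 chromosomes × 4000 markers, pool 200, 25
  decoys per bulk.
* Parental read-ratio compositions are asymptotic (expectation) claims:
  they are measured on large simulated pools (3000 non-mutant / 10000
  mutant individuals) with ~10⁵ reads at one marker, so that the
  reported ratio reflects read-sampling convergence rather than the
  binomial composition noise of a small pool.  With a 200-seedling pool
  the same ratios hold in expectation but carry ~5–10% pool noise per
  replicate.
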