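# Methods

This note documents the models, conventions and numerical choices behind
`zmpipe`, and what the synthetic-data generators do and do not emulate.

## Coordinates and anchors

All internal coordinates are 0-based half-open (BED convention); GFF3 input
(1-based closed) is shifted on read. A gene's 5′ anchor is its first
transcribed base — `start` on the plus strand, `end − 1` on the minus
strand — and offset 0 sits on that base, with upstream positions strictly
negative. Both metaplot anchors use the *inward* convention: positive
offsets point into the gene from either end, so a profile runs from
−upstream (outside the feature) to +into (inside). This matches the usual
presentation of ends-aligned plots, where both the 5′- and the 3′-aligned
half put "into the gene" on the positive axis. Overlapping annotations are
all retained and contribute independently; no de-duplication is applied.

## Methylome analyses

**Context calling.** A cytosine's context is read from the strand-oriented
trinucleotide: CG if the next base is G, CHG if the base after next is G,
CHH otherwise (H = A, T or C). Minus-strand sites read the
reverse-complemented trinucleotide. Sites whose trinucleotide contains N or
runs off the chromosome are undeterminable and excluded.

**Weighted levels.** Every aggregate (bin, window, locus) is the pooled
level `Σc / (Σc + Σt)` over contributing cytosines, never a mean of
per-site fractions. Pooling weights sites by coverage and keeps
low-coverage sites from dominating; sites with `c + t = 0` contribute
nothing. Replicates are pooled by summing counts before testing — there is
deliberately no per-replicate dispersion model (see Limitations).

**Metaplots.** 100-bp bins from 2 kb outside to 5 kb inside each feature
end by default. Each cytosine of the requested context contributes its
counts to the bin of its inward offset, once per feature whose window
covers it; bin values are pooled weighted levels, missing where no
coverage.

**Differential methylation windows (DMWs).** Chromosomes are tiled with
fixed, non-overlapping 50-bp windows starting at coordinate 0 (the tiling
origin is unstated in the source analyses; coordinate 0 is the
deterministic choice). Each window is tested with a two-tailed Fisher
exact test on the pooled 2×2 table `[[c_mut, t_mut], [c_wt, t_wt]]`.
Windows with an absolute level difference below 0.10, or overlapping a
transposon annotation, are excluded; output separates methylation gain
from loss and includes a per-direction p-value histogram. The two-tail
probability is the minimum-likelihood convention: the sum over all tables
with the observed margins whose point probability does not exceed the
observed table's (this is also scipy's convention, which backs the single
shared implementation).

**KDE.** Gaussian kernels with Silverman's rule bandwidth by default.
An explicit bandwidth admits single-observation input (the density is one
Gaussian bump); without one, at least two distinct values are required
because the rule needs a spread.

## ChAP-seq enrichment

**Midpoints.** Single-end 50-bp reads are converted to nucleosome
midpoints by adding 75 bp (half of an average 150-bp nucleosome) to the
read's 5′ end *in read orientation*: `start + 75` on plus, `end − 1 − 75`
on minus. A `literal_start` flag reproduces the strand-naive reading
(leftmost coordinate + 75) for comparison. Off-chromosome midpoints are
dropped and logged; midpoint counts otherwise conserve read counts exactly.

**Track.** IP and input midpoint densities are each scaled to counts per
million midpoints and subtracted base-wise (IP − input). The normalization
is a package choice: raw subtraction is meaningless for unequal library
sizes, and CPM makes the track invariant to uniform library scaling.

**Gene scores and clustering.** TSS score: mean enrichment over [0, 500) bp
from the TSS. Body score: mean over [1 kb, L − 1 kb) in transcription
orientation, defined only for genes of length L ≥ 2.1 kb so the window
cannot touch the two end peaks. Heat-map rows sort by the wider
[500, L − 500) body window. Metaplots omit, per gene, all data beyond
L − exclusion from the anchor (default exclusion 1 kb) so short genes'
opposite-end peaks do not contaminate body averages. The nine-cluster
partition takes marginal terciles independently on the TSS and body scores
(ties broken by gene id for determinism), yielding approximately
equal-sized groups when the two axes are not strongly dependent;
pseudogenes are removed to their own group first.

## Ecotype-aware differential expression

The mutant line is a mosaic of WS and Col genomes. The procedure:

1. **Scaffolds.** Each diagnostic SNP gets a pair of 75-bp scaffolds (37 bp
   flank each side) differing only at the central base.
2. **Assignment.** Reads are matched exactly (no mismatches, both
   orientations). A read counts for an ecotype only if it matches that
   ecotype's scaffold at an offset covering the central base and does not
   occur anywhere in the other scaffold; reads matching both (i.e. not
   spanning the SNP) are uninformative and discarded.
3. **Filtering.** A SNP is kept if it lies in an exon of a gene longer
   than 200 bp, at least one read length (36 bp) from both exon ends, and
   carries at least 10 assigned reads summed over all samples.
4. **Genotyping.** Heterozygous when the minor allele holds ≥ 10% of reads
   and ≥ 2 reads (robust to ~1% sequencing error at depths 10–100;
   configurable); otherwise homozygous for the majority; untyped below 10
   reads.
5. **Smoothing.** WS read-count contributions `ws/(ws+col)` at heterozygous
   SNPs are smoothed with a centered rolling mean of 20 SNPs, restricted to
   maximal runs of heterozygous SNPs: smoothing across a homozygous
   breakpoint would blend unrelated regions. Windows truncate at block
   edges.
6. **Partitioning.** A gene's genotype is the majority genotype of its own
   retained exonic SNPs (ties → heterozygous); genes without retained SNPs
   take the nearest retained SNP's genotype within 50 kb of the gene
   midpoint (ties → lower coordinate). Heterozygous genes split counts by
   the nearest heterozygous SNP's smoothed contribution; the two parts
   conserve the total bitwise (the remainder representation is chosen so
   the float sum reproduces the total exactly). Unlinkable genes are
   flagged and excluded.
7. **Testing.** Fold changes use replicate-mean RPKM per ecotype with a
   0.5-RPKM pseudocount on both terms (zero-handling choice). Significance
   uses counts rescaled to the smallest library (gentler than per-million
   scaling on the read counts the exact test depends on), summed over
   replicates, partitioned, rounded half-to-even only at the test stage,
   and Fisher-tested as gene-vs-rest-of-library per ecotype. A gene is DE
   if either ecotype has |log₂FC| ≥ 1 with p < 0.001, or both do in the
   same direction with p < 0.005 each; contradictory qualifying directions
   yield `none` with a warning. With a degenerate all-Col genome the whole
   chain provably reduces to a plain per-gene Fisher DE test.

The gene-vs-rest-of-library 2×2 construction is isolated in one function
(`fisher_de_test`) so it can be swapped if a different table is preferred.
Raw p-value thresholds are applied as stated — deliberately no
multiple-testing correction, matching the procedure being reproduced.

## Association statistics

Spearman's rho uses average ranks for ties; p-values are two-sided
permutation probabilities (seeded, default 10,000 shuffles, +1-corrected).
Box-plot summaries use linear interpolation of the empirical CDF for
quartiles (the numpy default) and Tukey whiskers at the most extreme
observations within 1.5 IQR of the box. Direction classification is strict:
log₂FC > 0.5 is up, < −0.5 is down. Set-overlap significance reuses the
same Fisher implementation on the overlap 2×2 table. Group median ratios
are exposed as report fields only — they depend on the dataset at hand and
are not test targets.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under their seed and feed back through
the package's own readers.

* **Genome**: i.i.d. nucleotides at 36% GC (Arabidopsis-like), with
  non-overlapping genes, transposons and pseudogenes placed left to right
  with 2.2–3 kb intergenic gaps. No repeats, no isoforms, no N runs.
* **Methylome**: per-site truth by feature class — genic CG ramps linearly
  from 0.05 to a 0.40 body plateau over 1.5 kb (the canonical gene-body CG
  shape), CHG/CHH stay at background inside genes; transposons are
  methylated in all three contexts (CG 0.80 / CHG 0.40 / CHH 0.10), and
  the mutant condition perturbs only transposon levels, with CHH halved —
  genic patterns untouched. Coverage is Poisson around the nominal depth;
  methylated counts are binomial. Planted 50-bp windows override the truth
  for sensitivity studies; they are planted in CHH because cytosine density
  there (~10 per 50-bp window at this composition) makes every window
  testable, whereas ~18% of windows carry no CG dinucleotide at all.
* **ChAP**: input midpoints uniform at 30 per kb; IP midpoints follow
  baseline × (1 + TSS Gaussian peak + body plateau), with three designed
  tiers per axis (amplitudes 0/8/20; body levels 0/1.5/4). Tier spacing is
  part of the design: the 500-bp TSS window sees only ~15 input midpoints
  at this depth, so adjacent tiers must sit several standard errors apart
  for the designed classes to be statistically recoverable at all. Reads
  are emitted so that the midpoint estimator inverts them exactly.
* **RNA-seq**: per-gene counts are Gamma-Poisson (negative binomial) with
  size 100 — mild biological overdispersion appropriate to an inbred
  line's replicates. 36-mers are sampled uniformly across each gene; every
  read draws a parental haplotype with the genomic block's WS probability
  and carries that haplotype's alleles at covered SNPs, reverse-
  complemented on minus-strand reads. Blocks cycle WS / Het(0.5) /
  Col / Het(0.25) along the chromosome. No sequencing errors, no adapter
  or conversion artifacts, no positional bias.
* **Responsiveness**: a Gaussian copula tied to the measured body scores,
  with the Pearson parameter set to `2·sin(π·ρ_s/6)` so the *Spearman*
  correlation hits the target; a monotone transform maps to a 0–100 score,
  Dirichlet shares give tissue/abiotic/biotic subscores, and the score
  quantile extremes are labelled housekeeping / hypervariable.

Because replicate counts are only mildly overdispersed and reads are
error-free, passing tests demonstrate correctness of the computational
chain — not that the pooled exact test controls error rates on strongly
dispersed biological replicates (it does not; that is a property of the
procedure being reproduced, noted below).

## Verification problem sizes

The acceptance script and test suite use: exhaustive Fisher enumeration
over all 2×2 tables with both row margins ≤ 25 (123,201 tables, agreement
to 1e-9); 200 genes at 20× depth for metaplot recovery (±0.03 per bin);
100 planted Δ = 0.30 windows at 50× depth against a ~6,000-window null
(sensitivity ≥ 0.9 at p < 0.001, null significant fraction ≤ 0.5%); 450
genes at 30 midpoints/kb for nine-cluster recovery (≥ 95%); 300 genes with
3v3 replicates, mean 50 reads/gene and 30 genes planted 4-fold up for DE
recovery (recall ≥ 0.9, false positives ≤ 1%); n = 5,000 for copula rank
correlation (±0.05); and small full-pipeline runs for byte-level
determinism. These sizes make each check statistically decisive while the
whole battery completes in a few minutes on one CPU.

## Known limitations

* The pooled-count Fisher DMW and DE tests ignore between-replicate
  dispersion and apply no multiple-testing correction; both are faithful
  to the reproduced procedure, not recommendations.
* Metaplots weight each read (pooled counts), not each gene; a
  gene-weighted variant would need per-gene normalization first.
* Genotyping thresholds and the 50-kb SNP search radius are heuristics for
  the unstated steps of the original procedure; both are configurable.
* The KDE grid is finite, so the density integrates to 1 only to numerical
  tolerance over the evaluation range.
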