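# zmpipe

Analysis pipeline for studying how the histone variant **H2A.Z** relates to
DNA methylation and transcriptional responsiveness in *Arabidopsis
thaliana*, built for genomicists who need the complete chain — from
per-cytosine bisulfite calls, ChAP-seq read intervals and allele-mosaic
RNA-seq through to association statistics — as tested, reusable, scriptable
components.

The pipeline covers four analyses:

1. **Context-resolved methylome profiling.** Per-cytosine calls in the
   three plant contexts (CG, CHG, CHH; H = A, T or C) are aggregated into
   *weighted* methylation levels `Σc / (Σc + Σt)`, ends-aligned 100-bp
   metaplots over genes and transposons, and fixed 50-bp genomic windows.
   Differential methylation between mutant and wild type is tested per
   window with a two-tailed Fisher exact test on pooled counts, keeping only
   windows with at least a 10% level difference and no transposon overlap.
2. **H2A.Z ChAP-seq enrichment.** Nucleosome midpoints are estimated by
   shifting each 50-bp single-end read's 5′ end 75 bp in read orientation
   (half a 150-bp nucleosome); IP and input midpoint densities are
   normalized to counts per million and subtracted base-wise (IP − input).
   Genes get a TSS score (mean enrichment 0–500 bp from the TSS) and a body
   score (1 kb after the TSS to 1 kb before the 3′ end; genes under 2.1 kb
   are discarded) and are partitioned into nine clusters by marginal
   terciles on each score, with pseudogenes split out into their own group.
3. **Ecotype-aware differential expression.** The mutant line is a genomic
   mosaic of the WS and Col accessions, so cis differences between the
   accessions masquerade as mutant effects. Reads are assigned to parental
   alleles by exact matching against 75-bp SNP scaffolds, SNP regions are
   genotyped (WS / Col / heterozygous), heterozygous read-count
   contributions are smoothed with a rolling 20-SNP window, per-gene counts
   are partitioned into WS- and Col-derived parts, and each ecotype is
   tested separately: a gene is differentially expressed if either ecotype
   shows a two-fold change with P < 0.001, or both ecotypes show a two-fold
   change in the same direction with P < 0.005.
4. **Association statistics.** Spearman rank correlation with permutation
   p-values, log₂ fold-change binning, box-plot summaries, ±0.5 log₂
   up/down classification, gene-set overlap tests and kernel-density traces.

A first-class synthetic-data module generates every input with planted
structure (designed methylation profiles, enrichment tiers, allele mosaics
and fold changes), so the whole pipeline is testable end to end without any
external downloads.

## Worked example

Simulate a small study and run every stage:

```sh
zm run --out demo --seed 1
cat demo/stats_summary.tsv
```

which prints (the numbers are computed from the simulated data and are
reproduced exactly by any re-run with the same seed):

```
#statistic	value
spearman_rho_body_vs_responsiveness	0.3886079466518477
spearman_permutation_p	0.0009995002498750624
n_genes_up	6.0
n_genes_down	0.0
```

Here the synthetic design planted six 4-fold upregulated genes, and all
six (and nothing else) come back as `up`. Responsiveness scores were drawn
with a target rank correlation of 0.33 to the measured H2A.Z body
enrichment; the estimate 0.39 over the 60 body-scored genes is within
sampling error of the target, and the permutation p-value is the smallest
resolvable with 2,000 permutations. `demo/` also contains the differential-methylation windows
(`dmw.tsv`), the enrichment track (`enrichment.bedgraph`), the nine-cluster
table (`chap_clusters.tsv`), the full DE results (`de_results.tsv`) and a
provenance manifest with parameter and file checksums; a re-run with
unchanged inputs and parameters skips cached stages.

Every subcommand (`zm sim|annot|meth|chap|de|stats|run`) is a thin wrapper
over library functions in `zmpipe.*`, so the same operations are available
programmatically:

```python
from zmpipe import methylome, simulate
import numpy as np

rng = np.random.default_rng(0)
genome, models = simulate.generate_genome(simulate.GenomeDesign(n_genes=50), rng)
calls = simulate.generate_methylome(genome, models, simulate.MethylomeDesign(),
                                    depth=20, condition="wt", rng=rng)
profile = methylome.ends_aligned_metaplot(calls, models, context="CG")
```

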