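# vlincworks

Quantification and functional annotation of **very long intergenic
non-coding RNAs (vlincRNAs)** from 5'-capped tag data.

vlincRNAs are contiguous regions of intergenic transcription of 50 kb or
more (median ~83 kb) with no overlap to annotated genes on the same
strand. Because their 5' ends are imprecisely annotated and often sit in
retroviral LTR repeats with poor mappability, the classical CAGE recipe —
summing capped-tag counts in a window around the transcription start
site — systematically under-measures them. This package implements the
alternative: **internal counting**, which exploits post-transcriptional
recapping of cleavage products and sums tags across the whole masked
transcript body, together with the downstream battery of analyses that
turns those measurements into functional annotation:

- **Expression.** Strand-specific tag counting over masked bodies (gene
  exons and rRNA repeats excluded irrespective of strand), scaled
  RPKM-style: `raw / (informative_reads x length) x 1e9` for genes and
  `x 1e11` for vlincRNAs, where *informative reads* are uniquely aligned
  non-rRNA tags on the ordinary chromosomes.
- **Gene building.** A vlincRNA is a *standalone* transcript when on each
  side (5' and 3') either no same-strand gene lies within 50 kb or every
  such gene is separated from it by a chromatin insulator element;
  standalone vlincRNAs are merged strand-specifically into vlincRNA genes.
- **Neighbour correlation.** Every vlincRNA-gene and gene-gene pair is
  classified into four configurations (same-strand upstream/downstream,
  opposite-strand head-to-head / tail-to-tail) and eight distance bins;
  co-expression is summarised as two-stage medians of Spearman rho and
  stratified by insulator separation — the test of *cis*-activation.
- **Cancer/pluripotency metrics.** RMECN — the ratio of a vlincRNA's
  maximum expression across cancer samples to its maximum across normal
  samples — compared between LTR-promoter and nonLTR-promoter classes,
  with a label-permutation null, maximum-location contingency tests,
  tag-mass fractions, top-N class enrichment and differentiation
  time-course trend tests.
- **Regulators and targets.** miRNA-target anti-correlation (surrogate
  pri-miRNA expression from a +/-1 kb window around the pre-miRNA),
  OCT4/SOX2/NANOG binding status of assigned promoters, TF-vlincRNA
  correlation across embryonic-stem differentiation time courses, and
  ChIP-seq flank enrichment against random non-overlapping genomic
  regions.
- **GO enrichment.** Two-level: per-vlincRNA term lists from genes
  correlating at |rho| >= 0.35 (kept at unadjusted p < 0.05), then
  subset-vs-background hypergeometric enrichment over those vlincRNA-level
  annotations with BH-FDR control; plus a generic interval-overlap
  enrichment with an intergenic binomial correction.

A first-class **synthetic-data generator** produces a complete fixture
world — annotation tracks, sample table, latent expression with planted
Gaussian-copula correlation structure, and per-sample tag sets — so the
entire pipeline runs and is validated without any downloads. The
generator's defaults mirror the study design the package targets (class
mix scaled from 399 normal / 332 cancer / 92 stem / 10 immortalized
samples, ~83 kb median vlincRNA length, LTR fraction of promoter-assigned
vlincRNAs ~0.36).

## Worked example

```python
from vlincworks.simulate import SimulationConfig, simulate_world
from vlincworks.quantify import build_expression_matrix
from vlincworks.annotate import annotate_vlincs, LTR, NONLTR
from vlincworks.classmetrics import rmecn, label_permutation_test
from vlincworks.genes import designate_all

world = simulate_world(SimulationConfig(seed=1))
expr = build_expression_matrix(world.tagsets, world.bundle)
anns = annotate_vlincs(world.bundle)

calls, vlinc_genes = designate_all(
    world.bundle.vlincs, world.bundle.genes, world.bundle.insulators)
print(f"standalone vlincRNAs: {sum(c.standalone for c in calls)} / {len(calls)}")
print(f"vlincRNA genes after strand-specific merge: {len(vlinc_genes)}")

results, medians, _ = rmecn(expr, world.samples, anns)
print(f"median RMECN  LTR: {medians[LTR]:.3f}   nonLTR: {medians[NONLTR]:.3f}")
observed, p, _ = label_permutation_test(expr, world.samples, anns,
                                        n_perm=999, seed=2)
print(f"label-permutation ratio {observed:.2f}, p = {p:.4f}")
```

prints

```
standalone vlincRNAs: 76 / 80
vlincRNA genes after strand-specific merge: 76
median RMECN  LTR: 2.187   nonLTR: 0.618
label-permutation ratio 3.54, p = 0.0010
```

76 of the 80 simulated vlincRNAs are standalone (the four planted next to
a same-strand gene without an intervening insulator are not), and none of
them overlap, so merging leaves 76 single-member genes. The LTR class was
simulated with a 2x expression boost in cancer and stem samples; at this
fixture's size (17 LTR / 31 nonLTR promoter vlincRNAs, 60 samples) the
median RMECN ratio is noisy around that target, but the observed
LTR/nonLTR ratio of 3.54 exceeds all 999 label permutations, giving the
smallest achievable p-value of 1/1000.

The same flow is available from the shell:

```bash
echo "seed: 1" > cfg.yaml
vlincworks run-all --config cfg.yaml --out run1/
```

which writes the expression matrix, annotation, standalone calls, the
Table-style correlation summaries, class metrics, miRNA/TF reports and GO
enrichment under `run1/`, plus a `manifest.json` of every output.

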