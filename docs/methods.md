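# Methods

This note documents the models, conventions and numerical choices behind
`vlincworks`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate model and interval algebra

All coordinates are 0-based, half-open `[start, end)`, BED-native; GTF is
converted on read. A single convention everywhere removes the usual
off-by-one failure classes. Three consequences are worth stating
explicitly:

- A tag whose 5' end equals a fragment's start is counted ("on the
  border"); one equal to the exclusive end coordinate is not. Users
  importing externally produced alignments in a 1-based-inclusive dialect
  should shift coordinates on read, not flip the counting rule.
- Adjacent (touching) intervals merge: half-open adjacency is a zero-
  length gap, and the merged unit is a single contiguous transcribed
  region.
- Two transcripts are *separated by an insulator* only if an insulator
  element lies wholly within the gap between their facing ends. An
  insulator overlapping either transcript does not separate them — the
  conservative reading of "occurred between them", chosen because a
  barrier element inside a transcription unit has no defensible
  barrier interpretation for that unit. Overlapping transcripts have no
  gap and are never separated.

## Expression quantification

Expression is tag density over the feature's *effective* span:

- genes: the union of annotated exons (length = summed exon lengths);
- vlincRNAs: the body minus all gene exons and rRNA repeats on either
  strand (sense short-gene signal and antisense exon signal are both
  contaminants), optionally minus EST 5' ends +/-1 kb (same strand) or
  promoter elements +/-1 kb (either strand) when testing robustness to
  internal initiation.

Counting is strand-specific and sums multiplicities; sequencing channels
of one biological sample are concatenated before counting, which makes
channel structure invisible (an invariant the tests check). RPKM-style
scaling uses 1e9 for genes (per 1 M informative reads per kb) and 1e11
for vlincRNAs (per 100 M informative reads per kb); the two scales exist
only to keep both value ranges readable and cancel in every rank-based
statistic downstream. Features with zero effective length are dropped.

The RNA-seq-style counter gives a read fully inside a fragment credit 1
and a border-crossing read credit 0.5, mirroring common fractional
assignment; it exists to support CAGE-vs-RNAseq comparisons on fixtures.

Strand calling for unstranded vlincRNA annotations is a simple majority
vote of body tags; exact ties return an unresolved sentinel and the
feature is excluded from TSS-dependent analyses.

The 5'-density profile uses a +/-5 kb window in 500 bp bins around the
annotated 5' end (the right body boundary for minus-strand features),
reported 5'->3'. Named outlier features can be excluded.

## Standalone designation and vlincRNA genes

Per side (5', 3') of a vlincRNA, the side is *clear* when no same-strand
gene has a body-to-body gap <= 50 kb, or when every such gene is
insulator-separated from the vlincRNA. A vlincRNA is standalone when both
sides are clear; the call records which clearance applied (far/far,
insulator/insulator, mixed). Decisions embedded here:

- Only same-strand genes can block: an antisense neighbour is by
  construction a different transcription unit.
- "Within 50 kb" is inclusive at exactly 50 000 (a flag flips it); the
  distal definition (no gene within 50 kb on either side, either strand)
  conversely counts a gap of exactly 50 000 as distal, following the
  "at least 50 kb" phrasing.
- Short genes contained inside the body (legal for vlincRNAs) block
  neither side — they are not "in the 5' or 3' direction".
- Distance endpoints are body-to-body, not TSS-based: body coordinates
  are the only boundaries known for every annotation source.

Standalone vlincRNAs are merged per (chromosome, strand); each vlincRNA
gene records its member ids, and merging is idempotent.

## Neighbour configurations and correlation tables

Same-strand pairs are classified by where the gene lies in the feature's
transcriptional orientation; opposite-strand pairs are head-to-head when
the two 5' ends are the nearer pair of ends, else tail-to-tail, with ties
broken toward head-to-head. Distance is the nearest-end gap at 1 bp
resolution; overlapping opposite-strand pairs get distance 0 and fall in
the closest bin (the only coherent choice once overlap is allowed).
Distance bins are left-inclusive: 0-1, 1-5, 5-10, 10-20, 20-30, 30-40,
40-50, >50 kb, with the open bin bounded by a search horizon (default
200 kb for vlinc-gene pairs) so the pair set stays finite.

Aggregation is a two-stage median: per feature, the median rho over its
neighbours in a cell; then the median across features. Cells backed by
fewer than a configurable minimum of features (default 3; the bundled
pipeline reports at 1 because the default fixture plants one pair per
cell) report no median but keep counts. Non-computable correlations
(constant expression vectors, common in sparse data) are dropped, never
imputed.

## Class metrics

RMECN = max expression over cancer samples / max over normal samples,
per promoter-assigned vlincRNA; stem and immortalized samples are excluded
from both maxima. Medians are compared between the LTR and nonLTR
promoter classes. Ratios undefined because the normal maximum is zero are
excluded from medians and counted. RMECN is scale-invariant, so any
global normalisation choice cancels.

The permutation null permutes cancer/normal labels and recomputes the
LTR/nonLTR ratio of median RMECN; the p-value uses the (r+1)/(n+1)
estimator so "p < 0.001 at 1000 permutations" is exactly reproducible.
Maximum-location counts break ties by first sample position
(deterministic; ties are measure-zero for continuous data and warned
about otherwise).

The time-course trend test is an ordinary least-squares regression of the
tag-mass fraction on the time index, reporting the regression F-test
p-value halved for the one-sided decreasing alternative; an increasing
slope reports an N/A sentinel (the claim under test is specifically a
decline), and an exactly constant series reports p = 1. A Mann-Kendall
alternative was considered and rejected as the default because the
F-on-linear-trend reading is the only standard F-test that fits a
monotone-trend claim at a handful of time points.

## Regulators, targets, GO

Surrogate pri-miRNA expression is the sense-strand tag count in the
pre-miRNA +/-1 kb. The random-target control draws, per miRNA, an equal
number of genes without replacement from the expressed-gene pool; the
real-vs-random contrast is a one-sided KS test (real lower).

TF coupling is evaluated per factor over five groups (no-promoter,
LTR/nonLTR crossed with ChIP+/-) as Spearman rho against the TF's own
transcript across ordered time points (at least 4 required).

Random-region enrichment draws non-overlapping fixed-length regions
uniformly across chromosomes by rejection sampling, erroring when the
genome cannot host the request.

GO enrichment uses the classic unconditional hypergeometric per term (the
DAG-conditioned variant is version-sensitive and was deliberately not
used), ancestor-closed annotations with the root excluded, unadjusted
p < 0.05 for the per-vlincRNA term lists, and BH-FDR at the subset level.
The intergenic binomial correction approximates each query interval's
overlap probability as (target footprint + query length) / intergenic
length; the expectation and the directly counted genic overlaps can be
supplied externally, which reproduces a printed computation exactly
regardless of the approximation.

## Synthetic data

The generator plants every structure the pipeline is meant to detect:

- **Geometry.** Planned neighbour pairs occupy widely separated slots on
  chromosome 1, realizing each (configuration, distance, insulator)
  request exactly; remaining vlincRNAs are packed gene-free on
  chromosome 2 (distal by construction), followed by the miRNA block and
  an unplanned gene cluster. Decoy short genes, rRNA repeats and EST 5'
  ends exercise masking without disturbing distal bookkeeping. The
  default world is 2 chromosomes x 12 Mb, 300 genes, 80 vlincRNAs and 60
  samples (class mix scaled from 399/332/92/10) and runs through the full
  pipeline in well under two minutes.
- **Correlation.** A Gaussian copula with log-normal marginals; a target
  Spearman rho maps to the copula's Pearson r = 2 sin(pi rho / 6), making
  planted rank correlations exact in expectation under any marginal
  transform. Each feature may sit in at most one planted block (pair,
  miRNA family, TF coupling, class boost); a double claim raises with the
  offending block named. Promoter-bearing vlincRNAs are therefore drawn
  only from the unplanted set.
- **Class structure.** LTR vlincRNAs get a multiplicative boost (default
  2.0) in cancer and stem columns, so the LTR/nonLTR ratio of median
  RMECN recovers the boost. TF-bound LTR vlincRNAs track a declining TF
  trajectory across a 16-point differentiation time course at rho 0.8;
  miRNA targets couple at rho -0.4 to their miRNA's surrogate feature.
- **Tags.** Per-feature counts are Poisson with depth-scaled means
  (default 50 000 tags per sample plus 5 000 uniform background tags);
  positions mix a 5' peak (half the mass in the first 500 oriented bases)
  with a linearly decreasing body density, plus a 1% antisense flip. A
  30% subset of vlincRNAs carries its true peak 6-20 kb downstream of the
  annotated start, emulating the imprecise, repeat-confounded 5' ends
  that motivate internal counting — this is what makes the internal mode
  beat the 5'-flank mode on fixtures, as it does on real data.

What the generator does **not** emulate: mappability and sequence
content, batch effects, isoform structure beyond a single model per gene,
overdispersion beyond Poisson, and any correlation structure it was not
asked to plant. Passing tests therefore demonstrate that the statistical
machinery recovers planted structure at realistic sizes and noise levels,
not that real tag data satisfies the generator's assumptions.

Fixture sizes used by the validation suite are chosen so Monte-Carlo
error is small against each check's tolerance: copula recovery is checked
at rho 0.8 with 833 samples (estimator SD ~0.013 against a +/-0.08 band),
and RMECN boost recovery at 2000 vlincRNAs and 833 samples (SD of the
log ratio of medians ~3% against a +/-15% band). The category medians of
the 80-vlinc default world are far too noisy for that check — a property
the worked example in the README shows rather than hides.

## Numerical conventions

- All enrichment tests are one-sided "greater" by default; two-sided
  variants exist behind flags.
- All p-values lie in (0, 1]; empirical permutation p-values can never
  be 0 by construction.
- Spearman on a constant vector returns NaN ("not computable") and every
  downstream median or distribution step drops NaNs.
- BH-FDR is the standard step-up with a running minimum from the largest
  p down; ties and order preservation are oracle-tested.
- Every random draw flows from one root seed through named integer
  substreams (annotation, expression, tags, per-stage offsets), so a
  config plus seed reproduces every output byte-for-byte.

## Limitations

- BAM input is not parsed; tag sets enter as in-memory tables or the tags
  BED dialect. Real-data use requires converting alignments to 5'
  positions upstream.
- The neighbour-pair horizon truncates the >50 kb bin; statements about
  that bin are statements about pairs within the horizon.
- The intergenic overlap expectation is a documented approximation (see
  above) that understates overlap probability when the target set is
  fragmented relative to the query length.
- The GO layer ships a synthetic ontology for fixtures; running against a
  real GO release requires supplying the parent map and gene associations
  in the package's plain-dict form.
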