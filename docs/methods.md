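# Methods

This note records the statistical model behind each stage, the defaults
and why, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Differential expression

Counts K_fs for feature f in sample s are modeled as negative binomial
with mean μ_fs = q_f · sf_s and variance μ + α_f μ². The contrast is
always two groups (wild type vs one mutant, or signal-IP vs dead-IP), so
the estimator is closed-form rather than an iterative GLM fit; for the
reported quantities (group means, log2 ratio, Wald z) the two coincide,
and the closed form is exactly reproducible and deterministic.

**Size factors** are median-of-ratios: the per-feature reference is the
geometric mean over samples (restricted to features observed in every
sample; `pseudo_reference=True` lifts the restriction for sparse data),
and each sample's factor is the median ratio to that reference. Factors
are then rescaled to geometric mean 1, which pins the normalized scale
without affecting any ratio-based quantity. A consequence worth knowing:
globally doubling all counts leaves the size factors unchanged and
doubles the normalized counts, so borderline features can change call —
depth is information, and no count-level method is exactly
depth-invariant.

**Dispersions** are estimated per feature by method of moments on
normalized counts within condition groups, α̂ = max(0, (s² − μ)/μ²)
with the residual variance pooled across groups. Information is shared
across features through a mean-dispersion trend a₀ + a₁/μ fitted by
least squares to the positive raw estimates; the final value is the
geometric combination α̂^(1−w)·trend^w with weight w = 0.5
(configurable). A raw estimate of exactly zero means "no overdispersion
detectable with these few replicates", not "Poisson"; such estimates are
censored at the trend value before combining, because a literal
geometric combination with zero collapses the variance and destroys
tail calibration (about half of all features hit zero at 4 residual
degrees of freedom). With this censoring the 2000-feature null
simulation gives 5–6 % of raw p-values below 0.05.

**Testing.** log2FC = log2((mean_T + c)/(mean_C + c)) with pseudo-count
c = 0.125 (stabilizes ratios when one group is near zero; configurable).
The standard error propagates the NB variance of each sample's
normalized count through the log2 of the pseudo-count-shifted group
mean; z = log2FC/SE is compared two-sidedly to the standard normal.
Features with no counts anywhere are reported with undefined p.
Optional LFC shrinkage multiplies each estimate by τ²/(τ² + SE²), where
τ² is the excess of the empirical log2FC variance over the mean squared
SE (a zero-centered normal prior fit by moments). Shrinkage is **off by
default**: the published thresholds are applied to plain fold-change
estimates, and shrunk output is flagged in `attrs`.

**Filtering and FDR.** Benjamini–Hochberg is applied only to features
passing a mean-count filter. `independent_filter` implements a fixed
base-mean quantile; the pipeline default (`filter_quantile="auto"`)
scans quantiles 0–0.95 in steps of 0.05 and keeps the smallest quantile
maximizing the number of adjp < α discoveries, which is how the
standard tool chooses its threshold. The fixed-quantile variant is kept
because a fixed 25 % cut systematically removes truly downregulated
low-expression features (the effect itself lowers their base mean) and
biases the down-regulated share of discoveries.

**Calling.** Thresholds default to adjp < 0.05 and |log2FC| ≥ 1
(inclusive); a strict mode (> 1) matches the alternative wording used
for some analyses, and the stringent preset adjp < 0.0002 is exposed in
the pipeline config. Both comparators are reported by the recount
harness because published counts do not always say which was used.

## Covalent-target calling

The dead-IP (catalytic-dead bait) is the control group; enrichment
log2FC > 1 (strict) with adjp < 0.05 defines a call, ranked by
ascending adjp with ties broken by larger enrichment, then feature id —
fully deterministic. The length correlation (Pearson r of log2
enrichment vs log10 length) uses **all detected RNAs**, not only calls,
over spliced mRNA length by default; pre-mRNA length and raw-length
scale are available by flag since either convention is defensible.
Note the exchangeability limit: a null feature with high true dispersion
can by chance produce a clean several-fold split with small within-group
spread, and no within-group estimator can tell it from a genuine
low-dispersion target at three replicates; at the default conditions
this yields roughly 2–3 false calls per thousand features, which is why
target lists are ranked rather than treated as exhaustive.

## Transcript features

Coordinates are 1-based fully closed throughout, as in GTF/GFF3. The
reader accepts both attribute dialects, uses only exon and CDS records,
merges abutting/overlapping exons, and fails hard (with a line number or
transcript id) on malformed lines, CDS outside exons, or unknown
strands. Features: mRNA length = Σ exon lengths; pre-mRNA length =
genomic span; UTRs measured in spliced coordinates on the transcript's
own strand, CDS taken at face value with no stop-codon adjustment
(annotation dialects disagree; face value is reproducible). Transcripts
without a CDS have undefined UTRs (written "NA") and are excluded from
UTR/CDS comparisons but retained in mRNA/pre-mRNA/exon statistics. Gene
"length" means the pre-mRNA span of the longest isoform, which is also
the representative isoform (ties to the smallest transcript id).

## Feature enrichment

Group comparisons use the two-sided Mann–Whitney U: exact enumeration of
all assignments when both groups have ≤ 8 values (correct under ties;
the two-sided p is the probability of a U at least as far from n₁n₂/2 as
observed), normal approximation with tie correction otherwise. Length
distributions are heavily skewed, which is why a rank test is the
default; a Welch t-test on log lengths is available by flag. Stars
follow the strict mapping **** < 10⁻⁴, *** < 10⁻³, ** < 0.01,
* < 0.05, else ns. Per-feature raw p-values carry the stars (matching
per-panel figure conventions); a BH column across features is appended
for rigor. The background defaults to all non-focal transcripts and is
overridable, since "background" can mean detected-only or
transcriptome-wide.

## Reciprocal isoforms

A gene qualifies when it has ≥ 1 significant down and ≥ 1 significant up
isoform at the calling thresholds; all down × up pairs are emitted, the
best pair (most negative × most positive log2FC) is flagged, and pairs
are ranked by combined effect so a curated subset is reproducible by
rank. The TSS is the first exon start (+) or last exon end (−); "same
start" means exact coordinate equality by default, with a configurable
tolerance in nt because annotation wobble exists. Isoforms of one gene
on different strands are an error naming the gene.

## Overlap statistics

For sets A, B in a universe of N genes the random expectation of the
intersection is |A||B|/N; the fold over random and the exact
hypergeometric upper tail P(X ≥ k) are reported together, plus both the
expectation and the observation as percentages of |B| (two quantities a
"probability of random overlap" label could mean — both are emitted and
labeled rather than guessing). The universe defaults to the number of
genes in the annotation and is overridable. Ortholog mapping keeps all
(source, target) pairs — no best-hit collapse — with an optional score
cutoff; unmapped members are counted. Venn regions for 2–7 sets are
keyed by membership bitmask and always sum to the union.

## Climbing assays

CI = Σ x·n_x / n_total over zones 0–5, exactly; summaries give mean and
SEM (sample SD/√n, 0 for a single trial) per genotype × week, at trial
level and optionally averaged per batch first, since protocols differ in
whether triplicates are averaged before testing. The downstream ANOVA is
deliberately not reimplemented; the tidy output feeds any stats package.

## Synthetic data

Each generator is a pure function of the config and draws from its own
child stream of the master seed (fixed block offsets), so outputs are
byte-identical across runs and adding one block never perturbs another.
Defaults define the study conditions: 2000 genes; isoforms per gene
1 + Poisson(1) capped at 6 (fly-like, average ≈ 2); mRNA length
log-normal (log10 mean 3.3, sd 0.35) split UTR5/CDS/UTR3 by
Dirichlet(1, 6, 3); intron lengths log-normal; 5 % non-coding
transcripts; NB counts with baseline log-normal (ln mean 4, sd 1.2 —
median ≈ 55 counts), dispersion log-normal (ln mean −2.5, sd 0.8),
library-size factors log-normal (sd 0.15); three replicates per
condition. Effects: 10 % affected transcripts, 67 % down, |log2FC| ~
N(2, 0.5) floored at 0.5, with effect probability increasing in
standardized log10 3'UTR length (logistic coefficient 1); the
catalytic-dead mutant's effect set nests inside the null's
(P(effect|null effect) = 0.43, P(null|effect) = 0.92) and the ΔRGG set
is small with 11 % overlap; 30 genes carry planted reciprocal pairs
(±2 log2FC, baseline floored at 150 so the pairs represent
well-expressed curated isoforms). The IP block plants ~3 % targets with
binding log-odds increasing in log10 mRNA length and log2 enrichment
N(2, 0.5). Disease sets of 200–600 "human" genes carry a planted
2.5-fold overlap with the focal down set through a mostly-1:1 ortholog
map with 10 % one-to-two records (the extra targets dilute the realized
fold to ≈ 2.4). Climbing means are equal across genotypes through week
5 and diverge afterwards (wild type 3.6 at week 7 vs ≈ 2.0–2.2 for the
null and catalytic-dead genotypes); each fly's zone is Binomial(5, μ/5)
so trial CIs are unbiased for the target mean.

What the generators do **not** emulate: isoform-level count
correlations from shared reads (isoform counts are independent given the
gene), GC/length bias in coverage, batch effects, outlier replicates,
and annotation errors. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
real-data artifacts.

## Problem sizes and test design

The test suite and the acceptance script run the default 2000-gene,
3-vs-3 configuration; aggregate recovery metrics (FDR, power,
down-share, recall/precision, fold, reciprocal-gene recovery) are
averaged over ten simulation seeds, which keeps the whole acceptance
run under a minute on one CPU while holding Monte-Carlo noise on each
aggregate to a few percent. Oracle checks (brute-force BH, per-base
feature classification, exact Mann–Whitney enumeration, Monte-Carlo
hypergeometric tails) are independent reimplementations frozen in the
tests, never calls into the code paths they check.

## Known limitations

* Two-group contrasts only; no covariates, batch terms, or outlier
  refitting.
* Normal-tail p-values at three replicates are slightly heavy in the
  extreme tail (dispersion-estimation noise); aggregate FDR is
  controlled (~0.07 at nominal 0.05) but single extreme p-values should
  not be over-read.
* The exact Mann–Whitney branch enumerates up to C(16,8) assignments;
  beyond n = 8 per group it switches to the tie-corrected normal
  approximation.
* The recount harness expects sheets already exported to TSV with
  columns `feature_id, gene_id, log2fc, adjp`; it does not read XLSX.
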