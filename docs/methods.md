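# Methods

This note documents the statistical procedures, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open.

## Coordinate and data model

All intervals are 0-based half-open internally; the only conversion happens
at the GFF3 boundary (1-based closed on disk). A single convention keeps
the 2 kb / 5 kb distance rules free of off-by-one errors. Unstranded
features (strand `.`) participate in overlap tests on both strands.
Edge distance between non-overlapping intervals is the gap in bases, so
touching intervals have distance 0 without overlapping — "genic" requires
a real ≥ 1 bp overlap, a touching feature is proximal.

Expression lives in an `ExpressionMatrix` (features × samples, unit-tagged
as TPM / RPM / count, with generation and replicate metadata and an
optional subgenome tag per feature). Methylation is a long-format
per-cytosine count table (chrom, 0-based position, strand, CG/CHG/CHH
context, methylated and total reads, sample) — counts, not ratios, because
the binomial-type tests need them.

## Expression patterns (PatternModel)

**Normalization.** Counts are normalized with DESeq2-style
median-of-ratios size factors (median over all-positive features of the
ratio to the geometric-mean reference). Total-count scaling (CPM) is
biased here by construction: transgressive features move a whole
generation's library total, which then distorts every fold change.
Median-of-ratios is robust to asymmetric differential expression as long
as a plurality of features is unchanged. `make_insilico_hybrid` retains
CPM when used standalone on raw counts.

**In-silico hybrid.** The mid-parent expectation. `mean` mode averages
normalized parental values replicate-by-replicate; `pooled-count` mode
subsamples each parental count library without replacement (multivariate
hypergeometric) to half the target depth and sums, conserving total depth
exactly and deterministically under a seed.

**Differential test.** A variance-moderated t-test on log2(normalized
value + 1): per-feature pooled variances are shrunk toward the
across-feature mean with a fixed prior weight of d₀ = 4 degrees of freedom
and the t reference gains those degrees of freedom. With 3 replicates a
plain Welch test is dominated by variance flukes; moderation is the
standard remedy (limma). `moderate=False` restores plain Welch, and
externally produced DESeq2 tables can be substituted through the same
record shape. Significance requires BH-adjusted p < 0.05 **and**
|log₂FC| ≥ 1.5 (transcripts/lncRNAs) or 1.0 (small-RNA loci).

**Classification.** Let sig/sign of HvsM, HvsP, MvsP, HvsMPV be given.
Precedence:

1. *no-change* — none of HvsM/HvsP/MvsP significant;
2. *transgressive-up/-down* — HvsM and HvsP both significant, same sign;
3. *ELD-M* — HvsM not significant, HvsP significant (ELD-P symmetric);
4. *additive* — MvsP significant, HvsMPV not significant, hybrid mean
   between the parents;
5. *ambiguous* otherwise.

ELD is tested before additive deliberately: with the |log₂FC| ≥ 1.5 gate a
hybrid sitting exactly on one parent is often also statistically
compatible with the mid-parent (at a 4-fold parental split the MPV is only
1.32 log₂ units from either parent), so an additive-first rule would
absorb most ELD calls. The Rapp-style twelve-bin sign code over
(HvsM, HvsP, MvsP) is always emitted so any alternative grouping can be
applied post hoc; the grouped label additionally uses the MPV comparison
because the in-silico hybrid exists precisely to test additivity.

## Dosage dependence (DosageModel)

Pearson correlation between a feature's expression and its subgenome's
dosage vector — A: (1/2, 2/3, 1), C: (1/2, 1/3, 0) across
maternal / hybrid / paternal. p-values come from the two-sided t
distribution with n − 2 df; BH adjustment runs per subgenome by default
(switchable to a global family). Labels: dd-positive / dd-negative require
R² > 0.64 and FDR < 0.05 (both strict), the sign of r sets the direction;
defined-r features otherwise are di; zero-variance features are
unclassifiable and excluded from the BH family.

Two input modes. `replicate-mean` correlates the three per-generation
means against the three dosages, matching the worked example
(r = 0.9685 → printed 0.96 by two-decimal truncation; truncation, not
rounding, reproduces the printed pair, and full-precision values are
always emitted alongside). `replicate` repeats the dosage per replicate
(9 points with triplicates) and is the mode to use for genome-wide
calling: a 3-point correlation has a single degree of freedom and its
p-value essentially cannot clear an FDR gate (the worked-example triple
itself has p = 0.16).

## Methylation

**Weighted level** of a region/context: Σ methylated / Σ total over valid
cytosines (per-site depth ≥ 5 reads) — the count-weighted ratio, not the
mean of per-site ratios, so deep sites carry their weight and the level of
a union of regions is the count-weighted mean of the parts.

**Metaprofile**: upstream 2 kb in 100-bp bins, body scaled to 20
proportional bins, downstream 2 kb; strand-aware mirroring for − features;
regions shorter than 20 bp contribute to flanks only (logged). Per-bin
values are pooled counts across regions, so the count-weighted mean over
bins equals the global weighted level of the profiled windows.

**DMR caller**: the genome is tiled into 200-bp bins per context; a bin is
testable when both groups have ≥ 5 valid cytosines (both readings of the
five-cytosine rule — per-site depth and per-bin count — are enforced).
Pooled methylated/unmethylated counts are compared by a two-sided Fisher
exact test (the test is pluggable; pooled counts fit single pooled
libraries per line), BH-adjusted per context; a DMR needs padj < 0.01 and
a level difference > 0.3 / 0.2 / 0.1 (CG / CHG / CHH), direction recorded
as hyper/hypo for group 2 vs group 1. Symmetric CG sites are not merged
across strands by default (`merge_cg_strands` collapses − onto + one base
left when wanted).

## Integration

Cis pairs use inclusive edge distance (≤ 5 kb lncRNA, ≤ 2 kb phasiRNA);
trans co-expression is strict (> 5 kb or different chromosome, r² > 0.81).
All pair correlations are computed on log2(value + 1) across samples at
replicate level. Signal metaprofiles assign interval weights to bins
proportionally to base overlap, conserving total weight within the
profiled windows. Fuzzy c-means (fuzzifier m = 2, tolerance 1e-5 on the
membership shift, ≤ 300 iterations) runs on per-feature standardized
profiles from a seeded random membership start; the objective
Σ uᵐ‖x − v‖² is non-increasing by construction, rows of the membership
matrix sum to 1, and top-membership ties break toward the lowest cluster
index. miRNA→target tables are consumed as given (prediction is upstream).

## Synthetic data: what it emulates, and what it does not

The generator mirrors the three-generation design (allotetraploid maternal
× diploid paternal → triploid hybrid, 3 replicates per generation) with
one RNG stream per sub-generator spawned from the master seed, so
extending one generator never perturbs another's draws.

* **Annotation.** Each gene owns a 20 kb neighbourhood (3 exons / 2
  introns); lncRNAs cycle through antisense / intergenic / intronic /
  sense placements with margins that guarantee the class; siRNA clusters
  cycle genic / proximal / distal; TEs alternate between gaps and lncRNA
  overlap. Placement is deterministic given the seed; infeasible requests
  (chromosome too short, more lncRNAs than host genes) raise a packing
  error rather than silently overlapping.
* **Expression.** Planted class mix: no-change 0.32, additive 0.25,
  ELD-M 0.20, ELD-P 0.15, transgressive 0.04 + 0.04, with the high parent
  alternating inside each class — transgression is rare in real hybrids,
  and a direction-balanced mix is what keeps depth normalization
  identifiable. Parents split by 2.0 log₂ units (`effect_log2fc`);
  transgressive hybrids sit that far beyond the more extreme parent, on
  the log2 scale, so the |log₂FC| ≥ 1.5 rule is attainable by
  construction. Counts are negative-binomial (dispersion 0.05) with
  gamma-distributed per-sample depth factors clipped to ±20 %
  (`library_cv` = 0.1). At dispersion 0 the exact expected counts are
  emitted, making the noiseless limits (hybrid exactly at mid-parent)
  testable to machine precision.
* **Dosage series.** dd-positive means scale proportionally with the
  dosage vector, dd-negative with the reversed vector, di features are
  constant; replicate noise is multiplicative log-normal with σ = 0.15
  (a 15 % CV, typical of TPM replicate variation). TPM units, 3
  replicates per generation.
* **Methylation.** 200-bp bins cycling CG/CHG/CHH; baselines 0.6 / 0.3 /
  0.1; planted shifts 0.5 / 0.3 / 0.2 in a fixed fraction of bins (0.2);
  12 cytosines per bin; coverage Poisson(30) so ≥ 5-read sites dominate;
  per-site proportions Beta-distributed around the baseline with
  concentration 100 (near-binomial, as expected for pooled libraries).
* **ACRs.** True ACRs appear in every replicate with boundary jitter
  ≤ 10 bp; decoys appear in exactly one replicate; every other lncRNA gets
  a fully covering true ACR (a planted ACR-lncRNA).

Not emulated: genome sequence content, read-level data, mapping artefacts,
homeolog cross-mapping (C-subgenome reads in the AA parent), TE sequence
evolution, and any correlation structure between the layers (expression,
methylation and accessibility are planted independently). Recovery on
these simulations therefore demonstrates that the rules and statistics are
implemented correctly and have the stated operating characteristics under
their own assumptions — not that those assumptions hold in any particular
real library.

## Problem sizes and numerical choices

Default desk-scale runs: 300 features for pattern recovery, 200 for
dosage, 90 methylation bins (plus 1,000 null bins for the empirical null
rate), 60-gene annotations. These sizes make every recovery experiment a
few seconds while keeping class counts large enough for stable rates.
Boundary comparators follow the stated rules strictly (> 200 nt, > 50 bp,
> 50 %, > 1 read, < 2 kb, R² > 0.64, FDR < 0.05, padj < 0.01). Ties in TE
association break toward the first genomic position. Zero-variance rows:
r undefined → unclassifiable (dosage), p = 1 for identical groups in the
DE test, all-zero rows after standardization in clustering. The BH
adjustment is monotone in rank and capped at 1; it is *not* idempotent
under re-application (re-adjusting multiplies by n/rank again), so no such
property is relied on.

## Interfaces

The two genuinely statistical analyses follow the statsmodels idiom —
`PatternModel(matrix).fit() → PatternResults` and
`DosageModel(matrix).fit() → DosageResults`, each with `summary()` — while
rule-based annotation, simulation, methylation and integration are plain
functions over the shared data model. The `hybepi` CLI exposes
simulate / annotate / patterns / dosage / methylation / integrate /
run-all; stages communicate only through TSV/BED/GFF3 files so any stage's
inputs can be replaced by real upstream-tool outputs, and the run manifest
records the seed, every threshold, and a hash per output file (same seed →
byte-identical rerun).

## Known limitations

* The built-in DE test is a moderated t on log-transformed normalized
  values, not a count GLM; for published-scale inference import DESeq2
  results through the external-table route.
* The DMR Fisher test assumes pooled binomial counts; replicate-level
  biological variation (beta-binomial with low concentration) would
  inflate its type-I error, which is why the caller's empirical null rate
  is monitored on simulations and the test is pluggable.
* Three-point dosage correlations have no useful p-value; use
  replicate-level mode for calling.
* The 50 % ACR-coverage rule is read from the lncRNA side by default; the
  ACR-side reading is available (`acr_coverage_side="acr"`) because the
  convention differs between studies.
* miRNA target prediction, coding-potential scoring, GO enrichment and all
  read-level processing are out of scope; their outputs are consumed as
  verdict/pair tables.
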