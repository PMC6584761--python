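# Methods

## Scope and design

The package re-implements, as importable library stages joined by
tab-separated files, the computational core of a two-group (case/control)
lncRNA profiling study: transcript retention filtering, four-predictor
coding-potential consensus, FPKM quantification, pooled-count differential
expression, strand-aware positional overlap classification, dual-correlation
target prediction, 2^−ΔΔCt qPCR statistics and hypergeometric term
enrichment. Wet-lab steps, read alignment/assembly and the internals of the
coding-potential predictors are out of scope: the pipeline starts from
per-transcript counts, coverage and predictor scores. Because such studies
rarely deposit raw data, a first-class synthetic-data module generates every
input with planted ground truth; all quantitative claims made by the test
suite are claims about recovery of that planted truth.

## Coordinates and formats

All intervals are 0-based half-open internally. GTF input/output converts
to/from 1-based closed coordinates at the file boundary and is the inverse
of the reader on valid records; BED12 blocks are decoded to the same exon
representation. Intermediate tables are TSV with mandatory headers; the
count matrix carries its per-sample totals in a sentinel `TOTAL` row and
group labels as `sample:group` column suffixes, keeping each stage's input a
single self-describing file. Coverage is a per-transcript scalar interpreted
as mean per-base read depth (the retention rule "coverage > 1" does not
state units; depth is the assumption, documented here).

## Quantification and filtering

FPKM is the literal closed form 10⁶·C/(N·L/10³) with no pseudocount or
clipping. The retention filter applies the printed inequalities literally:
FPKM ≥ 0.5, coverage > 1 (strict), length > 200 bp (strict). The FPKM clause
aggregates over samples with `max` by default — the most permissive standard
reading, so a transcript expressed in either group survives — configurable
to `mean` or `all`. The filter emits a per-transcript audit row recording
which clause(s) failed.

## Coding-potential consensus

CPC/CNCI vote coding for scores strictly above 0, txCdsPredict strictly
above 500, Pfam on a pre-digested boolean hit. Scores exactly at a threshold
count as noncoding (the source thresholds describe coding as strictly
"greater than"/"over"; the tie side is a flag). Missing predictors abstain
rather than vote: with ≥ 2 abstentions the 3-of-4 consensus can never fire
and the transcript is reported `ambiguous`, never dropped. The vote is
per-record with no cross-record state, hence monotone: moving any score
toward the noncoding side never flips a lncRNA call to coding.

## Differential expression

The original analysis used a pooled-count DE tool whose exact internal
statistic (an MA-plot random-sampling test) is not re-derived here. The same
sampling-model family is used instead: counts pooled within each group and a
two-sided two-proportion z-test with pooled variance on k₁/n₁ vs k₂/n₂,
isolated in `pooled_proportion_test` so an alternative statistic can be
swapped in without touching decision semantics. Multiplicity is controlled
with Benjamini–Hochberg (the upstream tool's FDR method is unstated; BH is
recorded in output metadata and verified against a brute-force step-up in
tests). The fold change uses a 0.5 pseudocount on pooled counts only, never
in the test statistic. "Fold change ≥ 2.00" is applied two-sidedly
(|log₂FC| ≥ 1), consistent with both up- and down-regulated calls being
reported. Degenerate pooled proportions (0 or 1) give z = 0, p = 1. No
replicate-aware dispersion model is fitted — the pooling is deliberate and
matches the stage being emulated; it overstates significance relative to an
NB GLM when biological variability is large.

## Overlap classification

The ten classes are made mutually exclusive by a fixed cascade (first match
wins): lnc-span ⊆ single mRNA exon; lnc-span ⊆ single mRNA intron;
mRNA-span ⊆ single lnc exon; mRNA-span ⊆ single lnc intron; spans
intersect (partial overlap); otherwise no overlap. The `Anti` prefix marks
opposite strands; flipping both strands preserves a label and flipping one
toggles only the prefix (tested as an involution property). Containment is
closed inclusion — an interval exactly equal to an exon is "complete in"
it — and a transcript crossing its container's exon–intron boundary falls
through to partial overlap. `classify_all_pairs` uses a per-chromosome
interval tree over mRNA spans; every non-sentinel label implies span
intersection, so the index provably enumerates the same candidates as the
all-pairs brute force (asserted by exact set equality on random instances).

## Target prediction

Candidates are, by default, all (DE lncRNA × DE mRNA) pairs plus all
positionally overlapping pairs — published target tables include
positionally unrelated ("NA") pairs, so correlation is not restricted to
overlaps. Pearson is computed on FPKM across all samples, Spearman as
Pearson on mid-ranks; a pair passes iff both ≥ 0.6 (boundary passes).
Zero-variance vectors make the correlation undefined; such pairs are
reported with an explicit reason, never coerced to 0.

## qPCR statistics

Technical replicates are averaged on the Ct scale. The calibrator is the
mean ΔCt of the control group (the standard cohort choice; a single
calibrator sample is an alternative the function parameter admits).
Relative expression is 2^−ΔΔCt exactly, so adding any constant to all Ct
values of a sample cancels. Group comparison uses the two-sided Wilcoxon
rank-sum: exact null distribution when min(n₁, n₂) ≤ 12 and the pooled data
are tie-free, else the normal approximation with continuity and tie
correction. The exact path is verified against full enumeration of rank
assignments for all n₁+n₂ ≤ 10; the approximate path's size is verified by
a 1,000-replicate null simulation at the 28 vs 28 validation design
(rejection rate required within [0.03, 0.07] at α = 0.05).

## Enrichment

One-sided hypergeometric upper tail (identical to one-sided Fisher), term
gene sets intersected with the user-supplied background before testing,
BH correction across tested terms, ranked output with a top-20 view.
Background defaults in the pipeline to the transcripts surviving the
retention filter. Flat term files (GMT) only; no ontology-graph propagation
— results on hierarchical vocabularies will differ from tooling that
up-propagates annotations.

## Synthetic-data generator

The generator defines the study conditions the tests exercise.

- **Design defaults.** 12 case vs 12 control samples (the discovery design;
  28 vs 28 is the validation design and is used where stated), 10%
  differential transcripts at |log₂FC| = 2, NB dispersion 0.1, expected
  library size 10⁶ fragments/sample, 5% per-predictor coding-call error,
  planted target-pair Spearman 0.9. Library depth and dispersion are not
  published quantities; these are ordinary bulk-RNA-seq magnitudes and are
  configurable, not inferred.
- **Annotation.** One (lncRNA, mRNA) pair per overlap class is planted by
  construction — the contained feature is placed inside a chosen exon or
  intron — guaranteeing coverage of rare classes without rejection sampling.
  All other transcripts occupy disjoint slots. Lengths are log-uniform on
  [201 bp, 20 kb] so everything passes the length filter unless a test
  overrides the range (an override at ≤ 200 bp is refused, since the filter
  would annihilate the output).
- **Counts.** Gamma–Poisson (negative binomial) with per-transcript mean
  proportional to length × a log-normal(0, 1) expression factor, case-group
  means scaled by 2^(±log₂FC) for planted DE transcripts, and per-sample
  expected totals normalized to the configured library size (fixed
  sequencing depth). Planted target pairs are drawn through a Gaussian
  copula whose Pearson parameter is 2·sin(π·ρ/6), so the realized rank
  correlation centres on the requested ρ. Pair members' expression factors
  are floored at a moderate level — validated transcripts are well
  expressed — which keeps the discrete marginals off the low-count floor
  where rank ties blur the planted correlation. At the degenerate |ρ| = 1
  limit the second member is an exact monotone integer rescaling of the
  first, so ties align and Spearman is exactly ±1.
- **Ct tables.** Additive-normal on the Ct scale: reference Ct ∼ N(20,
  σ_ref), target Ct = reference + baseline ΔCt − log₂FC·1[case] + N(0,
  σ_tech), with σ_ref = σ_tech = 0.15 cycles by default.
- **What it does not emulate.** Fragment-level positional bias, GC effects,
  batch structure, outlier samples, correlated null transcripts beyond the
  planted pairs, and biological (between-subject) variance beyond the NB
  dispersion. Passing tests therefore demonstrate correctness of the
  computations and recovery under the stated noise model, not performance
  on real cohort data.
- **Determinism.** Every generator seeds its own `numpy` Generator from
  (config seed, stage index); identical configs give bit-identical outputs,
  which the end-to-end determinism test asserts at the file level.

## Problem sizes used by the automated checks

Simulation-based checks run at the design sizes stated above: 2,000
transcripts at 12 vs 12 for DE sensitivity (20 replicates for the null),
200 planted + 200 null pairs at 24 samples for target prediction, 1,000
replicates at 28 vs 28 for the Wilcoxon null, 500 transcripts × 20 seeds
for the interval-index/brute-force equivalence. These sizes were chosen as
the smallest at which the respective binomial noise makes the asserted
bounds meaningful.

## Known limitations

- The DE statistic is a specified stand-in within the same pooled-count
  family as the original tool, not a re-implementation of it; per-transcript
  biological variance is not modelled.
- The published headline counts (transcripts detected, per-class pair
  counts, specific validated fold changes) derive from unpublished patient
  data and are not reproducible; published magnitudes (e.g. the 5.6-fold
  validated effect) are used as planted effect sizes instead.
- Enrichment treats terms as flat sets; GO-style graph propagation is a
  documented extension point, as is parsing raw Pfam domain tables (the
  pipeline consumes a pre-digested boolean hit column).
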