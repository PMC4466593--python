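# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions at the edges.

## Differential expression

Intensities are analyzed on the log2 scale; linear-scale input is
transformed by `log2_if_linear` (an optional positive offset guards zero
intensities). Quantile normalization forces every sample onto the common
reference distribution — the vector of row means of the column-sorted
matrix. Within a column, tied values receive the mean of the reference
values over the tied rank span, so ties stay tied; this is the common
dialect, and it matters for the invariants: a column with ties carries tie-
block means instead of the raw reference values, so "all columns share
identical sorted values" holds exactly only for tie-free columns (the tests
check tied columns against a brute-force per-column oracle instead).
Quantile normalization assumes the bulk of the intensity distribution is
unchanged between samples; it is appropriate for genome-scale matrices
where a minority of features move, and inappropriate for toy matrices where
most features carry group effects — the hand-enumerable end-to-end fixture
therefore runs unnormalized (`run_de(..., normalize=False)`).

Per feature, a one-way ANOVA compares the two groups; with two groups the F
statistic is exactly the square of the pooled-variance t statistic and the
p-values coincide (verified to 1e-10 relative tolerance). Welch's
correction is intentionally not the default: the pooled test *is* the
two-group ANOVA. Degenerate features with zero within-group variance in
both groups get F = 0, p = 1 when the group means agree (no evidence; lets
constant spike-in rows pass through rather than erroring) and p = 0 when
they differ (the noiseless limit). Multiple testing uses Benjamini–Hochberg
step-up adjustment (via statsmodels), cross-checked against a brute-force
enumeration of the step-up minimisation.

Classification applies a `FilterSpec`: a p criterion (raw or BH-adjusted)
plus a linear fold-change floor compared against |log2fc|. Defaults:

| filter | p criterion | fold floor |
|---|---|---|
| gene reporting | adjusted p < 0.01 | any nonzero change |
| miRNA reporting | raw p < 0.001 | 1.5-fold |
| detection (validation) | raw p < 0.05 | genes none; miRNAs 1.5-fold |

The gene fold clause reduces to "log2fc ≠ 0": any nonzero change counts,
with significance carried entirely by the p filter. The miRNA p filter
applies to the raw p by default, with `use_adjusted` as a switch, because
the stringent per-feature threshold predates the FDR step in the workflow
it mirrors; both modes are echoed in output metadata. The 1.5-fold floor is
evaluated as the anti-logged difference of log2 group means (not the ratio
of linear-scale means); the two differ slightly and the choice is recorded
here because it is a genuine dialect decision.

## Consensus targets and hubs

The interaction table stores one record per (miRNA, gene) pair with one 0/1
flag per prediction source and `support` = number of flagging sources.
Duplicate rows are merged by OR-ing flags; a stored support inconsistent
with the flags is a schema error naming the pair. The consensus filter
keeps pairs with support ≥ 2 by default — the standard defence against the
high false-positive rate of individual sequence-based predictors — and is
idempotent, with filtering at k+1 always a subset of filtering at k.

Hubs are defined on distinct partners: a target-hub is a gene with ≥ 15
distinct predicted miRNA partners, a miRNA-hub a miRNA with ≥ 15 distinct
predicted targets. "Binding sites per target" is counted as distinct miRNA
partners because the table is pairwise; a per-3'UTR site count would need
positional predictions the format does not carry. Hub detection runs on the
consensus-filtered table by default (the filter precedes all downstream
analyses); `enforce_consensus=False` allows pre-filter counting for
comparison. Unknown miRNA ids in lookups warn rather than fail, since
expression arrays routinely probe miRNAs absent from prediction tables.

## Overrepresentation

All three enrichment analyses share one primitive: the one-sided Fisher's
exact test, p = P[X ≥ k] for X ~ Hypergeom(N, K, n), where N is the
universe size, K the set size in the universe, n the query size in the
universe and k the overlap. Query and set are trimmed to the universe at
test time (trimming logged, never done at load). Fold enrichment is
(k/n)/(K/N), reported as NaN when undefined (n = 0 or K = 0); k = 0 rows
are kept in the output for completeness but can never be significant. The
test is one-sided (greater) because the workflow reports
overrepresentation only; two-sided variants were considered and dropped to
keep significance aligned with fold enrichment > 1.

BH runs across one family per query list per analysis: the up and down
gene lists are corrected separately, matching the separate up/down
reporting of the workflow. The default universe is the annotation universe
(the collection's universe file, standing in for "all known genes" of the
organism); `universe_mode="measured"` switches to the genes present on the
array, a documented alternative since either convention is defensible.

Being discrete, the hypergeometric test cannot reject at exactly the
nominal level: under the null, P(p < 0.05) equals the largest attainable
level below 0.05. The calibration test therefore compares the empirical
rejection rate against that exact discrete law (computed by independent
big-integer enumeration) rather than against 0.05 itself, and separately
asserts the law never exceeds 0.05.

## Integration

Direction pairing follows negative regulation throughout: up-genes are
intersected with the consensus targets of down-miRNAs and vice versa, and a
DE miRNA counts as "commonly enriched" when its binding sites are enriched
in the opposite-direction gene list. Counts in the three-block summary are
genes (not pairs) for the intersection rows, with pair counts reported
separately; every reported count is the cardinality of a set emitted next
to it. Stage outputs carry the configuration fingerprint, and
`build_summary` refuses to combine outputs with mismatched fingerprints.

## The simulator

`SimulationParams` defaults define the desk-scale study the validation
suite runs on: 2,000 genes and 200 miRNAs on 4 + 4 samples (the two-group,
four-arrays-per-group design of the motivating experiments); baseline
log2 intensities N(8, 1.5²), residual noise σ = 0.5 log2 units; 15 % of
miRNAs planted DE with a ±1.5 log2-unit shift (a desk-scale analogue of
finding ~90 DE miRNAs among several hundred probed); each planted miRNA
represses a disjoint regulon of 20 genes with coupling β = 1
(gene shift = −β × miRNA shift, summed when the overlap option is used);
10 % of genes independently DE at ±1.0; ten prediction sources flagging
true pairs at 0.8 and non-pairs at 0.01 per source; 50 pathway sets of
10–50 genes oversampling expected-DE genes 4:1. An effect of 1.5 with
σ = 0.5 at n = 4 per group gives per-feature detection power 0.94 at
α = 0.05 — strong but not saturated, so recovery is a meaningful check.
One RNG stream is consumed in a fixed order (miRNA effects → gene effects →
noise → sources → pathways), making every artefact bit-reproducible from
the seed.

What the simulator does *not* emulate: probe-level effects, background and
batch artefacts, intensity-dependent variance, correlated noise between
features, sequence-based prediction structure (sources are independent
noisy oracles), or annotation incompleteness. Passing recovery tests
therefore demonstrate that the pipeline's logic is correct and calibrated
under its own model, not that real-array preprocessing concerns are
handled.

## Validation design

Two filter configurations play distinct roles in the recovery experiments.
The stringent reporting filters control the precision of the published
lists; at n = 4 per group their per-feature power is low by construction
(0.23 at raw p < 0.001; BH-adjusted p < 0.01 demands raw p-values a df-6
t statistic rarely reaches), so they are scored on empirical FDR, which
must stay ≤ 10 % (nominal 1 %). Recall-oriented metrics — planted-miRNA
recovery with correct direction (≥ 90 %), regulator ranking in the top
decile of inverse-direction binding-site enrichment, and the Jaccard
overlap (≥ 0.6) between planted and recovered inverse pairs — are scored
at the detection filters (α = 0.05, the study-level significance
convention). Scoring recall at the reporting filters would measure the
filters' deliberate conservatism, not the pipeline's correctness; the
reporting-filter recall is still computed and reported for transparency.

Problem sizes in the validation suite: the Fisher oracle sweep enumerates
every (N, K, n, k) with N ≤ 100 (9.0 × 10⁶ tuples) against exact
big-integer tail sums plus 2,000 random configurations up to N = 200; BH is
checked on 1,000 random vectors of length 1–200; normalization on 100
random matrices, half with injected ties; ANOVA calibration on 10,000 null
features; null enrichment on 500 replicates × 200 sets (universe 1,000,
sets of 50, queries of 60). These sizes give tight binomial confidence
intervals while keeping the whole suite in tens of seconds on one CPU.

## Known limitations

* Filters and fold changes are defined for exactly two groups (the ANOVA
  machinery itself generalises, but nothing downstream does).
* Enrichment treats gene sets as flat; no ontology DAG handling, no
  rank-based (GSEA-style) statistics, no pathway topology.
* The inverse intersection is evidence of *possible* regulation; with
  pleiotropic miRNAs and dense prediction tables many intersections arise
  by chance, and no per-pair significance is attached.
* Hub counts depend strongly on the prediction snapshot used; thresholds
  (≥ 15 partners) are conventions, not estimates.
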