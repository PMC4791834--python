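# Methods

## Problem and model

Members of a protein complex are co-regulated: when a cell type makes more of
a complex, it makes more of every subunit, so their log abundances correlate
strongly across proteomes. A *compositional* (stoichiometric) change is
different — one subunit deviates from the complex's common trend, e.g. a
paralog replacing its sibling in a complex variant. Testing raw abundances
confounds the two: a whole-complex abundance shift makes every member look
differentially expressed. The pipeline therefore works on *complex-wise
corrected* values.

Let x_{ps} be the median-centered log2 abundance of protein p in sample s.
Per protein, the relative abundance is r_{ps} = x_{ps} − T_p, where T_p is
the trimmed mean of p's per-condition means (trim fraction 0.2 per tail,
integer floor; the plain mean when nothing is trimmed). For a complex c with
n present members in sample s, the corrected value of member p is

    c_{ps} = r_{ps} − mean_{q∈c, q≠p} r_{qs} = (n·r_{ps} − Σ_q r_{qs})/(n−1).

Consequences used as test oracles: corrected values of a fully observed
complex sum to zero in every sample; adding a constant to all members
(an overall complex-abundance change) cancels exactly; and
c_p − c_q = n/(n−1)·(r_p − r_q). Proteins in several complexes get the mean
corrected value over those complexes; with two complexes the two residual
complex terms cancel in the average, so multi-membership does not bias the
corrected value, only mildly inflates its variance. A complex contributes
nothing in samples where fewer than two members are present.

## Differential testing

Each condition is contrasted against the unweighted mean of the other
condition means under a per-protein one-way layout, with the standard error
from the pooled residual variance (robust to unequal replicate counts; a
single-replicate condition still receives an effect). Variances are moderated
with the standard hierarchical empirical-Bayes model: residual variances are
assumed scaled inverse-chi-square around a prior (d0, s0²) estimated by
moment matching of log variances (digamma/trigamma equations, trigamma
inverse by Newton iteration). The posterior variance
s̃² = (d0·s0² + d_g·s²)/(d0 + d_g) enters the moderated t with d0 + d_g
degrees of freedom. d0 = 0 reproduces the ordinary t exactly; identical
variances give d0 = ∞ (pooled-variance t); zero-residual-df proteins are
excluded from the prior fit but still tested with (d0, s0²).

P-values are Benjamini–Hochberg adjusted *within each condition*. A member is
**variable** when adjusted p < 0.05 in at least one condition; a complex is
**variable** when at least 20 % of its *quantified* members are variable
(boundary included). Both thresholds are configurable.

## Decoy null model

Decoy resources reassign the pooled membership list to complexes of the
original sizes by seeded permutation; within-complex duplicates are repaired
by swapping with random positions elsewhere, which preserves the multiset of
occurrences and the size vector exactly. Because decoy "co-members" do not
share an abundance trend, the complex-wise correction cannot cancel their
shared variation, and planted member effects drown in the residual
complex-level noise: decoy variable-member counts stay at the alpha level of
the testing while real-resource counts saturate at the planted truth as
conditions accumulate. "Null expectation" in the benchmark comparison is
measured empirically on a matched dataset generated with no planted effects.

## Complex resource handling

Complexes are ranked by source (manual < COMPLEAT < CORUM < user), then by
size descending, then by id for determinism. The greedy redundancy filter
keeps a complex unless it shares ≥ 50 % of *its own* members with an
already-kept complex — the denominator is the lower-ranked candidate, which
removes near-subsets of the kept representative (the conservative reading of
an ambiguous rule; the alternative denominators keep strictly more
complexes). The minimum size (5 members) is applied before ranking. Ortholog
mapping drops unmapped members and expands one-to-many mappings before
re-deduplication.

## Small-sample statistics

- Exact rank-sum comparisons enumerate all C(n, n_a) rank assignments for
  n ≤ 12, valid under ties; the two-sided p doubles the smaller tail
  (min(1, 2·min tail)), matching the convention of the tie-corrected normal
  approximation used for larger samples. The deviation-based two-sided rule
  differs under ties because the null is then asymmetric; the doubled-tail
  rule was chosen for consistency with standard references.
- Fisher's exact test on set overlaps uses the two-sided
  sum-of-less-probable-tables definition with the sample odds ratio, plus the
  Jaccard index of the two sets.
- BH adjustment is the step-up procedure applied per condition; it is tested
  against a literal step-up oracle.

## Synthetic data

The generator defines the study conditions for every recovery test:

| parameter | default | rationale |
|---|---|---|
| conditions × replicates | 16 × 3 | 11 cell types + 5 temporal transitions, triplicates |
| complex sizes | uniform 5–30 | large curated complexes, minimum 5 |
| multi-membership rate | 0.10 | a modest fraction of shared subunits |
| variable fraction | 0.22 | observed fraction of variable members |
| effect size (log2) | 1.0 | two-fold change at one affected condition |
| noise sd (log2) | 0.25 | label-free replicate-level noise |
| complex-abundance sd (log2) | 1.0 | whole-complex variation across samples |

Entries are baseline + per-(complex, sample) shared term + planted member
effect + Gaussian noise. The shared term induces within-complex correlation
(median r ≈ 0.9 at the defaults, emulating strongly co-regulated members)
and is what the complex-wise correction must remove; effects are planted on
individual members so the correction must *keep* them. With the
complex-abundance term well above the noise, decoy complexes inherit enough
unshared variation that planted effects are not recoverable through them —
the intended null behaviour. Missingness can be injected completely at
random (default rate 0); real label-free missingness is abundance-dependent,
which the generator does not emulate, so the tests say nothing about
missing-not-at-random robustness.

Paralog pairs are planted inside a shared complex with equal-magnitude
effects at a shared condition, opposite-signed for switches. The matched
transcriptome gives a chosen fraction of planted cases (default 0.38; the
trend subfraction 0.15 and the miRNA-linked subfraction 0.45 follow the
observed proportions) a same-sign mRNA change clearing the 0.5 log2 floor,
with pre-adjusted p-values clear of the 0.05 boundary, so threshold behaviour
is unambiguous. The cohort generator plants a 53-protein signature with a
±0.75 log2 group shift at noise sd 0.5 (effect = 1.5 × noise) in a 7 vs 14
sample design over 6148 proteins.

## Signature classification

Leave-one-out nearest-centroid: held-out sample assigned to the group with
the nearer per-feature-mean centroid (Euclidean distance); exact distance
ties leave the sample unclassified and count as errors (conservative).
Feature sets of sizes 4–28 (step 4) are sampled 100 times per size from the
signature pool and from all quantified proteins (the random pool includes
signature members by default, matching the comparison against "all
quantified proteins"; a flag excludes them), and per-size accuracy
distributions are compared with the rank-sum test. Accuracy per size is the
mean over sampled feature sets, not pooled predictions; its standard error
is sd/√100.

## Transcriptional classification

A variable (protein, condition) case is `transcriptional_true` when the
mapped gene's mRNA changes with the same sign, |log2 fc| > 0.5 and adjusted
p < 0.05 at that condition; `transcriptional_trend` when the same holds but
p ≥ 0.05; otherwise `not_transcriptional`. Cases without a mapped gene or
without an mRNA record at the condition are `unclassifiable` — a missing
mRNA fold change is missing data, never a zero change. A transcriptional
case is miRNA-linked when some miRNA targeting the gene is significant
(adjusted p < 0.01) at the same condition with sign opposite to the mRNA
change.

## Problem sizes and numerical choices

Recovery tests run at 30–100 complexes, 8–16 conditions × 2–3 replicates, a
scale at which every pipeline stage's statistical behaviour (calibration,
power, decoy null) is already stable; the calibration suite pools 50
simulations. The trimmed mean uses an integer floor per tail; quantile
normalization assigns the mean order statistic interpolated at proportional
rank so that incomplete columns remain comparable, preserving the
missingness pattern and averaging assigned values over within-column ties.
Outlier replicates are *flagged* (nearest-correlation neighbour from a
different condition, ties resolved in favour of the same condition), never
auto-excluded, since the original exclusion criterion is a judgment call.

## Known limitations

- The generator's Gaussian, homoscedastic noise and MCAR missingness are
  idealizations of label-free data; passing recovery tests demonstrate the
  pipeline's statistical contracts, not robustness to instrument artifacts.
- Variable-complex verdicts depend on the quantified-member denominator;
  sparsely quantified complexes are noisy and are dropped below 5 quantified
  members rather than modelled.
- The decoy repair loop is stochastic; infeasible inputs (a protein occurring
  in more complexes than exist) raise an error, and pathological
  near-infeasible inputs are guarded by an iteration cap.
- mRNA/miRNA statistics are consumed as pre-adjusted tables; the pipeline
  does not re-model the transcriptome.
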