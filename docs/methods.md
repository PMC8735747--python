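# Methods

## Data model

The unit of analysis is a case-control study of a biallelic SNP summarised
by genotype counts: CC (wild-type homozygote), CT, TT (mutant homozygote)
in each arm. Counts are strictly integers — they are people — and a group
entering analysis must contain at least one individual. Subgroup labels are
free-form strings compared case-insensitively after trimming, so "Non-Asian"
and "non-asian" fall into one stratum. Input files are plain delimited text
(comma default, tab accepted) with a named header; no standard genetics
interchange format (VCF/PED) carries study-level aggregate counts, so a
small explicit schema is the honest choice.

## Genetic models

Each of the five models reduces the 3-genotype classification to a binary
exposure. The allele model treats the 2n alleles of n individuals as
independent observations — the standard convention for this test family,
and the one under which the simulator's log-additive generating process is
correctly specified. The heterozygote and homozygote models drop the
excluded genotype's carriers from the table entirely rather than erroring,
since "CT vs CC" defines a comparison between two genotype classes. A
derived table with an empty case or control margin (e.g. a group with no CC
and no TT individuals under the homozygote model) raises a degenerate-table
error rather than silently producing infinities.

## Hardy–Weinberg screening

The default test is the Pearson chi-square of observed genotype counts
against HWE expectations at the estimated allele frequency, on 1 degree of
freedom (three cells, one estimated parameter), **without** continuity
correction. This specific variant reproduces all four control-group
p-values printed for the glioma studies to three decimals (.274, .122,
.781, .125), which pins down the convention. An exact test (summing
conditional heterozygote-count probabilities no larger than the observed
one) is provided for small samples but is not the default. Only controls
are tested — departure in cases is expected under a true association. The
inclusion filter excludes a study when its control p-value is strictly
below the threshold (default α = .01); p exactly at the threshold is
retained. A monomorphic control group is reported as an error, not as
p = 1, because the test is undefined there.

## Effect estimation

Per-study effects are log odds ratios with the large-sample SE
√(1/a+1/b+1/c+1/d) and Wald CIs on the log scale — the combination that
reproduces the published single-study intervals (e.g. allele OR 0.73,
CI 0.50–1.08 for the one Non-Asian study). When a table contains any zero
cell, 0.5 is added to all four cells of that table only (Haldane–Anscombe).
The glioma fixture has no zero cells, so the correction never touches the
reproduced numbers; it matters for simulated data with rare alleles. CI
level defaults to 95% and is configurable.

## Pooling and heterogeneity

Fixed-effect pooling is inverse-variance; the random-effects estimator is
DerSimonian–Laird method-of-moments, chosen because it numerically
reproduces the published pooled results (allele OR 1.196 → 1.20, CI
0.93–1.54, p = .162). τ² is truncated at zero, which forces the DL result
to coincide bit-for-bit with the fixed-effect pool whenever Q ≤ df — the
regime of every Asian-stratum analysis here. The pooled-effect test is Wald
z against the standard normal (no Knapp–Hartung adjustment), matching the
published p-values. The headline estimate defaults to "always random",
mirroring how such analyses are conventionally reported; an optional
Q-gated rule (random iff the Q-test p < .10) is available. The published
description of that gate contains an evident typo (stating P **>** .1
indicates heterogeneity); the conventional P < .1 is used. A
Mantel–Haenszel fixed estimator with the Robins–Breslow–Greenland variance
is included as an alternative for sparse tables, but inverse variance
remains the default because the DL machinery is built on it.

With one study every pooling function is a passthrough (the study's own
estimate and CI), and Q, its p-value and I² are reported as not applicable
(None / "–") rather than zero — single-study subgroups are reported, not
suppressed, because that is how stratified tables are conventionally
printed.

## Subgroups and sensitivity

Subgroup analysis partitions by a metadata key and runs the full
model-fitting on each stratum; strata order follows first appearance.
No between-subgroup heterogeneity test is computed. Leave-one-out
sensitivity analysis re-pools each (k−1)-subset; on the fixture, omitting
the single Non-Asian study is by construction identical to the Asian
stratum, a set identity the test suite exploits as an oracle.

## Publication-bias tests

Egger's test is the classic unweighted OLS of the standard normal deviate
(log OR/SE) on precision (1/SE), with a two-sided t test of the intercept
on k−2 df — the variant implemented by the original Stata routine and by
metafor's `regtest(model="lm")`, against which this implementation was
verified to agree to full precision. No small-sample (Harbord) alternative
is provided. Begg's test standardizes each effect against the fixed-effect
pool using vᵢ* = seᵢ² − 1/Σwⱼ, computes Kendall's S by explicit pair
enumeration with tie-corrected variance, and applies the continuity
correction (|S|−1) for k < 10. Both tests are reported but never gate the
pipeline, and with k = 4 their power is very low — their p-values are
descriptive. On the fixture, Begg's p exceeds 0.05 under every model;
Egger's does under the allele, dominant and heterozygote models but falls
below 0.05 under the recessive and homozygote models (p ≈ .007 and .011,
confirmed against metafor), where the single opposite-direction study sits
at the low-precision edge of the funnel. The package reports what the data
show.

## Simulator

`simulate_studies` draws, per study, a true log OR from
Normal(ln ψ, τ²), control genotypes from a multinomial at exact HWE
proportions for the configured control allele frequency q, and case
genotypes from those proportions tilted by ψᵍ for g copies of T and
renormalized — the log-additive (multiplicative per-allele) risk model, so
the allele-model analysis is correctly specified and ψ is the estimand,
while dominant/recessive analyses of the same data deliberately exercise
model misspecification. Counts are drawn jointly per arm (not allele-wise),
so cases depart from HWE when ψ ≠ 1, as they should under a true
association. Default configuration mirrors the glioma application: k = 4
studies with the published per-arm sizes (205–815), q = 0.15 (the fixture's
control frequencies span 0.12–0.22), ψ = 1.3, τ = 0. Per-study substreams
are spawned deterministically from the global seed, so extending k leaves
earlier studies' draws untouched and identical (config, seed) pairs yield
byte-identical tables.

What the simulator does *not* emulate: linkage disequilibrium with
neighbouring markers, covariates and confounding, population
stratification, or genotyping error. Passing recovery tests therefore show
the estimators are correct for cleanly sampled multinomial counts under the
stated risk model, not that the pipeline is robust to those real-data
complications.

`recover_parameters` repeats simulate→analyze and reports mean pooled log
OR, empirical CI coverage, mean τ̂², and Q-test/pooled-test rejection
rates. Monte-Carlo sizes used in the test suite (2000 replicates for the
null rejection rate at the fixture's scale; 20 replicates of k = 20,
n = 2000/arm for consistency; a few hundred elsewhere) keep the whole suite
in a few seconds while leaving Monte-Carlo error well inside the asserted
bands. Note τ̂² is truncation-biased upward at τ = 0 (its mean is small but
positive); the tests document rather than deny this.

## Numerical conventions

Full precision is carried everywhere internally; rounding happens only at
render time (ORs to 2 decimals, I² to 1, p-values to 3 with "<.001" below
0.0005, matching epidemiological reporting style). Degenerate inputs have
explicit error types rather than sentinel values: monomorphic markers,
empty margins, too-few studies, and constant-precision Egger designs each
raise a distinct exception, and the pipeline degrades bias tests and
sensitivity analysis to warnings when the study count is too small instead
of failing outright (exit codes: 0 success, 2 validation, 3 degenerate
analysis).

## Known limitations

Only the five classical genetic models are implemented (no
Cochran–Armitage trend test); no meta-regression, cumulative
meta-analysis, trim-and-fill, or between-subgroup Q test; exact
(conditional) odds ratios are out of scope. Published tables for this
dataset contain two internally inconsistent entries (the Non-Asian
recessive interval and the Non-Asian homozygote p-value) that recomputation
from the genotype counts cannot reproduce; the package reports the
recomputed values.
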