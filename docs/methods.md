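# Methods

## Coordinates and the "begins inside" rule

All internal coordinates are 0-based half-open (the BED convention);
1-based VCF positions are converted on ingestion. For a left-aligned indel
the VCF anchor base is unchanged sequence, so the **first affected base**
is the 0-based anchor + 1. This is the point used for peak overlap, TSS
windows and selection-track matching: requiring the event to *begin* inside
a peak (`peak.start ≤ b < peak.end`) prevents a long deletion that merely
spans a site from being counted as affecting it. An `anchor` begin-rule is
available for sensitivity analysis (`begin_rule="anchor"` /
`--max-indel-len` companion flag in the pipeline config).

Only variants whose reference and alternate alleles differ in length are
indels; multi-allelic rows are split per alternate allele with dosages
recoded as the count of that allele, because every downstream statistic is
per-variant. The length filter is strict: `length < 200` bp.

## TSS windows

Two window classes anchor on the strand-aware TSS (interval start on `+`,
interval end − 1 on `−`). Signed distance d is negative upstream of the
TSS along the transcription direction and positive downstream.

* `upstream5k`: −5000 < d ≤ 0 — inclusive at the TSS-proximal edge,
  half-open at the distal edge.
* `flanking5k`: −2500 < d < 2500 — half-open away from the TSS on both
  sides.

Only "≤ 5 kb" is externally constrained; the exact boundary conventions are
this package's choice and are asserted in tests. One indel may be assigned
to several genes; per-gene totals count (indel, gene) pairs.

## Population differentiation

Derived-allele frequency is Σ dosages / (2 × called samples) per
population; missing genotypes are excluded pairwise, never imputed, and
samples without a population label (e.g. admixed cohorts deliberately left
out of the differentiation analysis) are skipped. The derived allele is the
alternate allele unless a per-variant flip set is supplied; δ is invariant
under orientation flips (property-tested), only the reported sign/direction
changes.

δ(i,j) = min over k≠j of |f_ij − f_ik|. Ties in the minimising population
are broken lexicographically. The selection threshold is either the fixed
convention 0.2 (boundary inclusive) or mean + 2 SD of the pooled δ
distribution; the SD is the population SD (ddof = 0) since the computed δ
set is itself the population of interest, and the 0.2 ≈ 2 SD
correspondence is approximate under either convention.

## Expression association

Spearman's r_s with mean-rank ties is computed as the product-moment
correlation of the rank vectors — the exact generalisation of the classical
1 − 6Σd²/(n³−n) shortcut, which is biased under ties and is kept (and
tested) only for the tie-free case. P-values use the t approximation
t = r_s·√((n−2)/(1−r_s²)) on n − 2 df, two-sided, because both up- and
down-regulation are of interest; |r_s| = 1 maps to p = 0 by convention. A
pair is non-informative (excluded and counted, not an error) when fewer
than 3 paired samples remain after pairwise-missing removal or either
vector is constant.

BH correction is applied once across all performed tests in a run rather
than per gene; the alternative is defensible, but pooling is the stricter
and simpler contract. A gene is "up" if any significant pair has r_s > 0
and "down" if any has r_s < 0, so a gene can appear in both lists.

The BH step-up is *not* idempotent — re-applying it to its own q-values
inflates them — so the tested invariants are monotonicity in sorted-p
order, q ≥ p and q ≤ 1, plus an exact cross-check against statsmodels'
`fdr_bh`.

## Enrichment

The Monte Carlo null redraws |subset| items without replacement from the
universe; p_mc = (1 + hits)/(n_sims + 1) (add-one smoothing, so the
resolution floor at the default 10,000 simulations is just under 10⁻⁴,
consistent with reporting "p < 10⁻⁴"). For single-label items p_mc
converges to the hypergeometric upper tail, which the test suite checks at
3 binomial standard errors. In the pipeline the TF-enrichment universe is
all peaks with at least one base in a TSS window of some gene, and the
category universe is all genes in the gene set; both are configurable by
calling the library directly, since the appropriate universe depends on
the question.

## Selection evidence

Track matching is a point query of the first affected base against score
intervals (the consumed tracks are window-based scores, so interval–
interval overlap would double-count); rank p < 0.05 strictly defines 95 %
confidence and p < 0.01 defines 99 %, with the minimum taken over all
metrics and populations.

The sweep profile stratifies samples into the two homozygote classes of
the focal variant (each must have ≥ 2 samples) and computes, per sliding
window, the mean per-variant **expected** heterozygosity 2p(1−p) from the
class allele frequency; the published figure this emulates leaves its
y-axis unspecified, so observed heterozygote fraction is available via
`het="observed"`. Defaults — span 100 kb, window 5 kb, step 1 kb — are
package choices exposed as parameters. The focal variant is excluded from
every window; windows without variants are NaN, not zero.

## Synthetic cohorts

The generator emulates the joint structure of the real inputs: TF-labelled
peaks placed in the 5 kb upstream of each gene's TSS, indels with a stated
fraction (default 0.7) seeded to begin inside peaks, geometric indel
lengths with mean 3 bp (real indel spectra are dominated by a few bp;
> 99 % of drawn lengths fall at or under ~20 bp), genotypes drawn
binomially per population under Hardy–Weinberg equilibrium from per-variant
frequencies (default cohort 246 AFR / 379 EUR / 286 ASN), and FPKM that is
lognormal around a per-gene baseline with injected cis effects acting
additively on log-FPKM per dosage unit (noise SD 0.5 on the log scale, so
an effect of 0.25 per dosage unit is half a noise SD). Swept regions
resample carrier genotypes from a frequency chosen so the carriers'
expected heterozygosity is scaled by the stated factor, and the selection
track marks overlapping tiles with rank p < 0.01.

What the generator does **not** model: linkage disequilibrium beyond the
injected sweeps, allele-frequency spectra shaped by demography, sharing of
peaks between genes, expression covariance structure (population
stratification, batch effects), or genotype error. Passing tests on these
cohorts therefore demonstrate the correctness and calibration of the
statistics under their stated assumptions, not robustness to the
confounders of real consortium data.

The worked fixture is fully deterministic and uses 50 samples per
population — 100 chromosomes each — so that alternate-allele counts of
34/11/12 yield the canonical frequencies 0.34/0.11/0.12 exactly (the
full-size population counts cannot represent those frequencies as exact
chromosome counts). Its δ(AFR) is 0.22 against the nearest population
(EUR at 0.12).

## Problem sizes and numerical choices

Test-suite simulations use cohorts of 465 samples (155 per population)
with 100–500 gene–variant pairs and 20 replicates for calibration and
power checks, and 10³ × 10³ random instances for the brute-force overlap
oracle; these sizes make the suite complete in well under a minute while
leaving Monte Carlo error small relative to the margins asserted. All
randomness flows from explicit integer seeds (`numpy.random.default_rng`);
the pipeline records its seed in the output manifest, and identical
configuration plus seed reproduces every output byte for byte. Degenerate
inputs are contracts, not crashes: empty peak files yield empty result
tables, populations with zero called chromosomes at a variant are flagged
missing and excluded from δ, and a pipeline stage failure aborts with the
stage name while keeping completed intermediates on disk.
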