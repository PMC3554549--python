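# Methods

## Model

The package tests whether a functional group (gene or gene set) separates
cases from controls in either of two complementary ways.

**Burden component.** Individual burden status is modeled as a Bernoulli
variable: 1 when the weighted variant burden reaches a threshold `T`, 0
otherwise, assumed i.i.d. within each group. The statistic is

    LLR_B = [ ℓ(k_c; n_c, p_c) + ℓ(k_t; n_t, p_t) ]
          − [ ℓ(k_c; n_c, p_pool) + ℓ(k_t; n_t, p_pool) ],

with `ℓ(k; n, p) = k ln p + (n−k) ln(1−p)` evaluated at raw counts and
add-one smoothed probabilities `p_c = (k_c+1)/(n_c+2)`,
`p_t = (k_t+1)/(n_t+2)`, `p_pool = (k_c+k_t+1)/(n_c+n_t+2)`. The returned
value is the magnitude of this log ratio signed by `sign(p_c − p_t)`:
positive when cases exceed the threshold more often, negative when
controls do, and exactly zero at equality. (The raw smoothed ratio is not
identically zero at `p_c = p_t` — e.g. `k=0, n=1` in both groups gives
`2 ln(8/9)` — so defining the directional statistic through the signed
magnitude is what makes balanced data score zero and the statistic
antisymmetric at fixed counts.) `T` is scanned over every distinct
positive observed burden ("at or above" semantics); only observed values
can change the counts, so this equals a scan over all real thresholds.
Ties are broken toward the smallest threshold. Note that the *optimized*
statistic is not antisymmetric under a label swap in general — the swap
turns the maximum over thresholds into a negated minimum — but it is
antisymmetric whenever a single candidate threshold exists (e.g. carrier/
non-carrier dichotomies), and the fixed-count statistic always is.

**Position component.** For a gene of `L` codons, a segmentation
partitions `[0, L)` into windows; interior windows have the nominal size
`w`, a leading window of length `offset` and a shorter trailing window
are retained so every codon belongs to exactly one window. For
(window size, shift) pairs (8,1), (16,2), (32,4), (64,8) each offset in
{0, s, …, w−s} yields one segmentation — 32 candidates per gene
regardless of length (duplicate partitions of short genes are retained to
keep the candidate count fixed). Window counts are compared through

    LLR_P = Σ_w [ x_c,w ln(θ_c,w/θ_pool,w) + x_t,w ln(θ_t,w/θ_pool,w) ],

with `θ_g,w = (x_g,w + 1)/(X_g + K)`. The maximizing segmentation is
selected per gene (first in enumeration order on ties); a gene set sums
per-gene maxima, genes without observed variants contributing zero. Counts
are unweighted; in the default `mutations` mode every allele copy counts,
in `positions` mode each distinct mutated codon counts once per group.

**Combination and inference.** The default combined statistic is the sum
of the two log-likelihood ratios; a `max` rule is exposed as an option
(the two readings of "burden or position"), and the permutation null is
valid for either. P-values use the add-one estimator
`p = (r+1)/(B+1)`, ties counting toward `r`, so p lies on the grid
{1/(B+1), …, 1} and is never zero. Every permutation re-runs the full
pipeline — threshold scan and segmentation selection — so the null
distribution reflects the same optimization applied to the observed
labels. All three statistics are scored against one shared permutation
stream, and stratified permutation (labels shuffled within strata,
per-stratum case counts preserved) supports structured samples. The
default `B` is 10,000; power simulations in this package use `B = 199`
for throughput, which makes 0.05 an exactly achievable level (10/200).

## Weights and genetic models

The allele-frequency weight is `1/√(2N q̂ (1−q̂))` at the beta-smoothed
pooled frequency `q̂ = (a_case + a_ctrl + α)/(2N + α + β)`, default
`Beta(1,1)` pseudocounts, `2N` chromosomes in the denominator. Because
`q̂` uses the pooled allele count it is invariant under label
permutation, so per-sample burdens are computed once per study.
Bioinformatics scores arrive from a file, must lie in [0, 1] (1 is
conventionally assigned to protein-truncating variants), default to 1
when absent, and can multiply the frequency weight (`product` mode).
Weights apply to the burden component only; position counts are always
unweighted. Genetic models: `additive` (contribution `g·s`) or
`dominant` (`s·1{g≥1}`); additive is the default everywhere.

## Simulation framework

The generator emulates etiology-driven case-control studies directly at
the level the statistics consume, rather than through forward-in-time
population simulation with selection:

* **Site frequencies.** Per-site minor allele frequencies are drawn from
  a mixture of log-uniform bands. `AA-like` (default): weights 0.60 /
  0.25 / 0.15 on (1e-4, 0.01), (0.01, 0.05), (0.05, 0.5) — a wide
  spectrum with rare, low-frequency and common mass. `EA-like`: weights
  0.95 / 0.05 on (1e-4, 1e-3), (1e-3, 0.01) — almost entirely rare, with
  ≥90% of sites below MAF 0.001. Defaults: 150 segregating sites on a
  500-codon (1500-base) gene, scaled proportionally for other lengths
  (one site per 10 coding bases, a density typical of deep resequencing
  of large cohorts). Sites occupy distinct codons, placed uniformly.
* **Genotypes.** `Binomial(2, MAF)` per site at linkage equilibrium
  (implemented as two independent haplotype draws), independent across
  sites and individuals.
* **Traits.** Gaussian liability `φ ~ N(Σ_j g_j·effect_j, 1)`;
  individuals with no causal variants draw from a standard normal, which
  naturally produces phenocopies and incomplete penetrance.
* **Etiologies.** Eight disease models plus a null: rare (causal MAF
  < 0.01, effect +0.5 per allele copy), low-frequency (0.01–0.05, +0.25),
  key-region (rare variants confined to 10 of 100 randomly designated
  10-codon segments of a 1000-codon gene, +1.0), common (one causal
  variant with MAF > 0.05, +0.25), and each with protective modifiers
  added (a 0.25 fraction of non-causal variants below MAF 0.05 get
  −0.5). A `null_fraction` (default 0.25) of qualifying variants is
  assigned zero effect, so causality criteria are necessary but not
  sufficient. The four effect sizes, the protective parameters and the
  null fraction are package defaults — chosen once as plausible
  liability-scale shifts for their frequency classes — and are all
  configurable.
* **Study draw.** Extreme-phenotype design: the top 1% of the population
  by trait forms the affected pool, the bottom 25% the unaffected pool;
  cases and controls are sampled from their pools without replacement and
  intermediate individuals never enter a study. A null study draws every
  trait from a standard normal.

Because traits depend only on causal-site genotypes and sites are
independent, the study sampler materializes population genotypes at
causal sites only and draws non-causal genotypes just for the sampled
individuals — distributionally exact under the generator's assumptions,
and what makes 100,000-individual populations affordable. An explicit
all-sites population path (`build_gene_set_population` /
`draw_case_control_study`) exists for small-scale work and is tested
against the same invariants.

**What the generator does not emulate:** linkage disequilibrium,
recombination, selection, demographic history beyond the shape of the
frequency spectrum, genotyping error, and covariate structure. Passing
power and calibration results therefore speak to the statistics'
behaviour under idealized exchangeable sampling, not to robustness
against confounding in real cohorts (for structured samples the
stratified permutation mode is the intended guard).

## Study conditions for the reported numbers

* **Null calibration:** 500 studies, one 500-codon gene, AA-like
  spectrum, 100 cases + 100 controls from a population of 10,000,
  B = 199. Sized to keep the statistic non-degenerate (about 11 carried
  alleles per individual) so permutation p-values are near-continuous on
  their grid; the rejection rate at 0.05 is checked against the binomial
  99% CI and uniformity with a Kolmogorov-Smirnov test.
* **Single-gene power:** rare etiology, 1000 cases + 1000 controls,
  population 100,000 (the smallest population whose 1% affected pool can
  supply 1000 cases), 250 replicates, B = 199, alpha 0.05.
* **Gene-set power:** 100 genes, 25 causal, etiologies drawn 10:1:1 from
  {rare, low-frequency, key-region} : {common} : {protective-containing}
  (uniform within category), 100 cases + 100 controls, population
  20,000, 250 replicates, B = 199, alpha 0.05.

Both power runs use allele-frequency weighting under the additive model.
Replicate counts and `B` keep a full run in the minutes range on a single
CPU; `estimate_power` derives an independent seed per replicate from one
master seed, so estimates are exactly reproducible.

## Numerical choices

* Probability and multinomial parameters are smoothed add-one; likelihood
  exponents use raw counts. Zero-count windows drop out of the position
  sum analytically, so only occupied windows are materialized; the full
  window number `K` still enters the smoothed denominators.
* The batched permutation engine evaluates the threshold scan via sorted
  cumulative case counts and the window statistics via integer-count
  table lookups; both are cross-checked in the test suite against direct
  per-call reference implementations and brute-force oracles, to 1e-9 or
  better.
* Tie-breaks are deterministic: smallest burden threshold, first
  segmentation in enumeration order.
* Missing genotypes load as 0 copies with a logged missingness count
  (burden semantics: variants demonstrably carried); multiallelic VCF
  records are split per alternate allele; variants outside every gene
  model are dropped with a logged count; monomorphic-in-study sites are
  retained but flagged, and contribute nothing to any statistic.
* Minus-strand gene models reverse exon walk order and within-exon
  offsets, so codon 0 is always the first coding codon of the mRNA; a
  trailing partial codon is indexed like any other.

## Known limitations

* The burden scan on weighted (continuous) burdens treats every distinct
  observed value as a candidate threshold; with allele-frequency weights
  this can mean one candidate per sample, which is exact but makes the
  chosen threshold itself noisy in small studies.
* No covariate adjustment; stratified permutation is the only structural
  control.
* Analytic p-values are not provided; everything is permutation-based,
  so the smallest achievable p is 1/(B+1) and group screens needing very
  small p-values need correspondingly large B.
* The common-variant etiology assigns its single causal variant without
  null-fraction thinning (thinning a one-element set would silence the
  whole etiology in a quarter of replicates).
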