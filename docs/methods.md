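# Methods

This note documents the models behind `chipscope`, the defaults that matter,
what the synthetic-data generators do and do not emulate, and the numerical
conventions chosen where the design was genuinely open.

## CHIP carrier calling

A somatic call's VAF is alt/(alt+ref). VAFs are only computed at sites with
total depth ≥ `min_depth` (default 20): at a clone VAF of 0.02 a depth of 20
gives an expected 0.4 alt reads, so anything shallower is pure noise; sites
below the floor are flagged rather than assigned a value. VAFs above 0.5 are
biologically possible (loss of heterozygosity, copy-number change) and are
retained but flagged.

Whitelist rules come in three kinds — `any_truncating` (nonsense/frameshift/
splice notation in the protein change), `listed_positions`, and
`listed_protein_changes`. This grammar covers the common per-gene curation
styles (loss-of-function genes vs. hotspot genes); users supply their own
curated gene list as TSV.

Carrier status per subject is the maximum VAF over that subject's
whitelisted calls, with the three-level factor none / low (≤ cutoff) / high
(> cutoff). The cutoff is **strictly** greater-than: a VAF of exactly 0.08
is "low".

### Cross-depth harmonization

Cohorts sequenced at ~80× (exome) detect smaller clones than cohorts at
~38× (genome), so raw carrier prevalence and VAF spectra are not comparable.
The harmonizer operationalizes "choose a cutoff that makes the
distributions nearly identical" as a grid search: for each candidate cutoff
c (default grid 0.02–0.20, step 0.005) the deeper cohort's carrier VAFs are
truncated to {v > c} and compared to the shallow-cohort reference by the
two-sample Kolmogorov–Smirnov distance; the minimizing cutoff wins, with
ties broken toward the smaller cutoff (retaining more carriers). The
comparison uses carriers only, not full cohort distributions. The shipped
default cutoff for exome-vs-genome harmonization is 0.08.

## Association statistics

* **SE reconstruction.** Published per-cohort estimates often print only a
  ratio and a two-sided Wald P. The SE is recovered as |log ratio| / z(p/2).
  Reconstruction from 2-significant-figure P-values carries rounding error
  that can shift pooled ratios by roughly ±0.01.
* **Fixed-effects meta-analysis.** Inverse-variance weighting on the log
  scale; pooled SE = (Σ1/sᵢ²)^(−1/2); two-sided P from the standard normal.
  Mixing log-OR and log-SHR scales is refused rather than silently pooled.
* **Logistic regression** is a statsmodels maximum-likelihood fit behind the
  module's interface; quasi-complete separation is detected (singular
  information matrix, or any coefficient beyond ±15 log-odds) and raised as
  an error naming the offending covariate rather than returned as a huge
  unstable estimate.
* **Ordinal (proportional-odds) regression** for autopsy grades: CERAD 0–3,
  Braak stage grouped 0/I/II → 1, III/IV → 2, V/VI → 3, and their composite
  (CERAD + grouped Braak, range 1–6). P-values compare the coefficient
  t-statistic to the **standard normal**, not a t-distribution — the
  convention used for these models in the neuropathology literature this
  package follows; with only two observed levels the model reduces exactly
  to logistic regression.
* **Survival.** Kaplan–Meier and the two-sided log-rank test (lifelines
  behind the interface; ties aggregated within distinct event times).
  Competing-risks (Fine–Gray) regression is deliberately *not* fitted here:
  cohort-level subdistribution hazard ratios are consumed as external
  estimates, because that fit belongs to specialized packages and only its
  outputs enter the pooling stage.
* **Stratified runs.** APOE genotypes bin as neutral (ε3ε3), low-risk
  (ε2ε2, ε2ε3) and high-risk (any ε4 allele); ε2ε4 goes to high-risk since
  it carries an ε4 allele. Gene-stratified runs compare each driver gene's
  carriers against all noncarriers. Degenerate strata (one outcome class,
  or separation) are skipped and recorded in the result.

## Mendelian randomization

Per-instrument ratio estimates βⱼ = Γⱼ/γⱼ with first-order delta SEs
σⱼ = se(Γⱼ)/|γⱼ| are the shared ingredient. IVW uses a multiplicative
random-effects model: the fixed-effects SE is inflated by √φ, where
φ = Σ(βⱼ−θ̂)²/σⱼ² / (k−1), floored at 1; φ is also reported as a crude
pleiotropy signal (MR-PRESSO-style outlier tests are out of scope). The
weighted median sorts ratio estimates, forms centered cumulative
inverse-variance weights sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2, and interpolates at s = 0.5;
its SE is a parametric bootstrap (βⱼ* ~ N(βⱼ, σⱼ), default 1,000 draws,
default seed 1234 — the estimator has no closed-form SE and this bootstrap
is the standard choice). Ties in βⱼ are broken by stable sort. MR-Egger is
weighted least squares of Γ on γ with an intercept, after orienting all
γ > 0; its residual dispersion is floored at 1 like IVW's. Allele
harmonization (effect-allele alignment, palindromic SNPs) is accepted as a
precomputed `flip` column, not inferred. Studies matching fewer than half
the exposure instruments are skipped.

## Brain chimerism

For a heterozygous somatic variant, 2×VAF estimates the fraction of mutant
cells. With `total` profiled nuclei, `mg` microglia and `non_mg`
non-microglial hematopoietic nuclei,

    mut_mg = round(total · VAF · 2 − non_mg)       (floored at 0)
    prop_mut_mg = mut_mg / mg

The subtraction conservatively assumes every non-microglial hematopoietic
nucleus is mutant; at low VAF this can overshoot, hence the floor at zero.
Rounding is round-half-to-even (Python's `round`); at the documented worked
example either rounding convention gives 759. Proportions can exceed 1
(the unadjusted value at the worked example is 103%); they are reported raw
with a `clamped` flag, and clamped values are available for plotting.

**Detection limit.** Amplicon VAFs (default minimum depth 500) are called
detected only above max(3/depth, upper 95% Clopper–Pearson bound of the
negative control's alt fraction). The negative control — the same primers on
a known non-carrier — bounds the PCR/sequencing error floor; without one the
3/depth floor applies with a warning.

**Confidence intervals.** Each replicate redraws the alt-allele count
~ Binomial(n_genomes, VAF) and the microglial count
~ Binomial(n_nuclei, pct_mg), recomputes the estimator in fraction form
(2·VAF* − non_mg_frac)/pct_mg*, and the 2.5/97.5 percentiles form the CI.
Defaults: n_genomes = 200,000 haploid genomes (100,000 template nuclei),
n_nuclei = 8,000 (a realistic single-sample median), n_sims = 10⁶
(tests use 10⁴). The non-microglial fraction is held fixed — it is a small
count whose sampling noise is dominated by the other two terms. Replicates
that draw zero microglia are dropped as uninformative for the ratio.
Sample-specific nuclei counts are used when known; 8,000 is the fallback.

**Composition statistics.** The MG/glia fraction is MG / (MG +
oligodendrocytes + astrocytes). Group differences are tested by
quasibinomial regression: a binomial GLM of (MG out of glia) on the group
indicator with dispersion estimated as Pearson χ²/df and Wald SEs inflated
by √φ̂ (verified to match R's `glm(..., family = quasibinomial)` exactly).
Blood–brain concordance is a Pearson correlation with P from
t = r√((n−2)/(1−r²)) on n−2 df. Sorting performance is summarized as fold
enrichment (sorted fraction / unsorted fraction).

## Synthetic-data generators

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; any derived seeds stay below 2³¹.

* **Cohorts.** Ages normal (default mean 70, SD 8) truncated to 45–90, with
  90 as a ceiling code for privacy-style capping. APOE genotype frequencies
  anchor to a published 2,437-person cohort table; the pooled ε2ε2/ε2ε3
  group (310) is split ~1:20 reflecting the rarity of ε2 homozygotes. CHIP
  prevalence is logistic in age (defaults give ~5% at 60, ~15% at 75, the
  published range for these cohorts); carrier clone VAFs are Beta(1.5, 20)
  truncated to (0, 0.5) — a right-skewed spectrum with most clones small, as
  observed in population sequencing; no published parametric form exists, so
  this is the package's choice. Case-control outcomes follow a logistic
  model with a planted CHIP odds ratio (default 0.64); longitudinal outcomes
  draw exponential AD and death times with the AD hazard scaled for
  carriers (default 0.63) and administrative censoring at 20 years.
* **VAF observations.** Read depth ~ Poisson(platform mean: 38× genome,
  80× exome), alt reads binomial, detection requires ≥ 3 alt reads (a
  common somatic-calling floor). This reproduces the depth-dependent
  sensitivity that motivates harmonization.
* **MR summary statistics.** Default 24 instruments; exposure effects
  half-normal (scale 0.08, offset 0.02 so no instrument is null); outcome
  effects θ·γ plus optional balanced or directional pleiotropy on 30% of
  instruments; planted θ = ln(0.90) forward, 0 reverse.
* **Brain samples.** Multinomial composition (default 7% MG, 0.5%
  non-microglial hematopoietic, remainder parenchyma); the bulk VAF is the
  exact inverse of the chimerism estimator at the planted mutant fraction;
  amplicon reads are binomial at that VAF with depth set to the template
  count (200,000) so that template-genome sampling — the noise source the
  CI simulation models — is the limiting stage. A negative-control sample
  is drawn at the background error rate (10⁻⁴).

What the generators do **not** emulate: linkage disequilibrium among
instruments, family structure within cohorts, site/batch effects,
misclassification of AD diagnoses, clonal evolution over time, sequencing
artifact modes (oxo-G, strand bias), and doublets or ambient contamination
in single-nucleus data. Passing tests therefore demonstrate correctness of
the statistical machinery under clean sampling models, not robustness to
every real-data pathology.

## Problem sizes in the test suite

The suite's simulation-based checks use sizes chosen to make the asserted
properties statistically decidable while keeping the default run fast:
planted-OR recovery at n = 5,000 subjects × 200 seeds; weighted-median
calibration over 500 seeds of 24 instruments; CI coverage over 500
replicates at 10⁴ inner simulations; log-rank type-I error over 2,000
null replicates. The acceptance script's quantities are deterministic
(closed-form arithmetic on documented inputs) and independent of the seed
argument it accepts.

## Known limitations

* Fine–Gray competing-risks fitting, family-clustered variance, MR-PRESSO/
  MR-RAPS/mode-based MR, and power calculations are intentionally out of
  scope; external estimates enter through `CohortEstimate`.
* The weighted-median bootstrap resamples ratio estimates, not the
  underlying (γ, Γ) pairs, so exposure-side uncertainty enters only through
  the ratio SEs (first-order delta method).
* SE reconstruction from rounded P-values propagates rounding error; the
  meta-analysis of printed estimates is accordingly accurate to about two
  decimals on the ratio scale.
* The chimerism CI conditions on the observed non-microglial count and
  assumes the amplicon library's effective template count; both are
  documented defaults rather than measured per sample.
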