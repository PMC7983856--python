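# Methods

This note documents the models implemented in `matingkit`, the numerical
choices behind them, what the forward simulator does and does not emulate,
and the design decisions that were genuinely open.

## The mixed-mating model and its EM estimator

A progeny array is the set of genotyped open-pollinated offspring of one
maternal plant. Under mixed mating, offspring *i* is selfed with probability
*s* and outcrossed with probability 1 − *s*; conditional on the maternal
multilocus genotype **m** and pollen-pool allele frequencies **p**, its
multilocus genotype likelihood is

    P(g_i | s) = s · L_self,i + (1 − s) · L_out,i,

where, per locus, `L_self` enumerates the four ordered maternal gamete pairs
(selfing kernel) and `L_out` sums the maternal transmitted allele (½ each for
a heterozygote) times the pollen-pool probability of the other allele.
Multilocus kernels are products over loci, which assumes loci are unlinked
and in linkage equilibrium — the same assumption a multilocus outcrossing
estimator always makes. Missing loci are dropped from the product.

**EM.** The complete-data problem treats each offspring's selfed/outcrossed
origin as latent. E-step: z_i = s·L_self,i / (s·L_self,i + (1−s)·L_out,i).
M-step: s ← mean(z_i). The observed-data log-likelihood is non-decreasing
every iteration (asserted in tests) and, this being a one-parameter mixture,
EM converges to the MLE. Convergence is declared when the log-likelihood
changes by less than `tol` (default 1e-8; the change in s is tracked but is
not the criterion). Because terminal EM convergence is sublinear where the
likelihood is flat, the fit ends with a bounded Brent polish of the same
objective, accepted only when it strictly improves the likelihood — so a
family whose likelihood is genuinely flat keeps the EM point (and `s_init`).

**Numerical choices.** s is clamped to [1e-9, 1 − 1e-9] during iteration and
snapped to exact 0/1 when within 1e-6 at the end, because fully selfing and
fully outcrossing families are real outcomes that should be reported as such.
Identifiability is diagnosed from the numerical curvature of the profile
log-likelihood at the optimum: |d²ℓ/ds²| ≤ 1e-6 flags a family whose selfing
and outcross kernels coincide (e.g., a heterozygous mother against a
half-half pollen pool at every informative locus).

**Mismatch handling.** An offspring locus where both kernels are zero means
the offspring carries no maternal allele there — a genotyping error, a
mutation, or an unamplified (null) allele. Such offspring-loci are demoted to
missing and counted (`n_mismatch_loci`); null alleles are deliberately not
modelled as a likelihood component. An offspring with no informative locus
left is excluded; a family with none raises an estimation error.

**Pollen pool.** Population allele frequencies are pooled from the maternal
genotypes of all families, plus 0.5 pseudo-counts for every allele observed
in any mother or offspring, renormalised. The smoothing guarantees that
every offspring allele has positive outcross probability. The pool is built
once per population and held fixed during every family's EM and bootstrap;
keeping families independent is what makes "resample offspring within the
family" a valid bootstrap. A locus with no genotyped individuals in a
population (failed amplification) simply carries no information and is
handled without configuration.

**Maternal genotype inference.** Mothers are often not genotyped. Per locus,
all unordered pairs of alleles observed in the family or present in the
pollen pool are scored by the mixed-mating likelihood of the entire offspring
set at a fixed reference s = 0.5 (neutral between the kernels; using the
family's own estimate would be circular), multiplied by a Hardy–Weinberg
prior from the pollen frequencies. Offspring a candidate cannot produce are
scored as rare error events (probability 1e-6) rather than skipped — skipping
would hand impossible candidates an artificially short likelihood product.
Ties break toward the higher prior, then lexicographic allele order. A
provided maternal genotype bypasses inference verbatim.

**Bootstrap.** B replicates (default 1000) resample offspring with
replacement within the family and refit; the pre-computed per-offspring
kernel likelihoods make each replicate a few vector operations. SE is the
sample standard deviation of tm replicates; the CI is the 2.5/97.5
percentile interval. B = 1 leaves the SE absent; replicates with no
informative offspring are redrawn up to 10 times, then dropped.

## Inbreeding across generations

`F` is the heterozygosity-deficit coefficient: per locus,
H_exp = (2n/(2n−1))(1 − Σp̂²) with n the genotyped individuals at that
locus; loci are combined as 1 − (Σ H_obs)/(Σ H_exp) weighted by n
(ratio of sums). This form, rather than a Weir–Cockerham ANOVA f, is used
because F here summarises small per-lineage samples where the simple
estimator is stable. Monomorphic loci are excluded and counted; all-monomorphic
data raises an error rather than returning 0.

`Fe = (1 − tm)/(1 + tm)` is the equilibrium inbreeding under constant mixed
mating, and `Fe − F` is the purging gap: under sustained mixed mating with no
selection the cohorts coincide, so a positive gap indicates selection against
inbred individuals between zygote and adult. At population level the
reported statistic is mean(Fe) − F.

A caveat the package makes explicit: when only progeny are genotyped, the
computable F is the progeny-cohort coefficient, not the adult-cohort value a
field study would obtain from adult tissue. Both per-family-progeny F and the
population-level pooled F are reported; neither is presented as an adult F.

## Inbreeding depression and the primary-selfing correction

δ = 1 − w̄s/w̄o with per-fruit fitness = seed-set × per-seed mass, averaged
over all fruits of mothers that have at least one fruit per treatment
(mothers lacking a treatment are excluded, with their ids listed).
"Mean fitness" defaults to the mean of per-fruit products — well-defined
under unbalanced fruit counts — with mother-level averaging available behind
`level="mother"` since the alternative reading is defensible. δ may be
negative (outbreeding depression) and is reported as-is. Seed mass is
defined as per-seed mean mass.

Because selfed zygotes die before genotyping at rate δ, the marker-based s
among survivors underestimates selfing at fertilisation. If r is the selfed
fraction at fertilisation, the genotyped fraction is s = r(1−δ)/(1−rδ);
inverting gives the correction

    r = s / (1 − δ + s·δ),

applied per family with the δ of that family's population. r is increasing
in both arguments, equals s at δ = 0, and maps [0,1] onto [0,1] for δ < 1.

## Statistical layer

- **Variance components** of herkogamy use the one-way random-intercept
  model (plant effect) fitted by profile REML: with θ = σ²_among/σ²_within,
  the within variance and grand mean profile out in closed form and the
  REML criterion is minimised over θ by Brent in log-space to ~1e-12. On
  balanced data this equals the expected-mean-squares ANOVA estimator to
  machine precision; on unbalanced data it agrees with a general mixed-model
  fitter to its own convergence tolerance (both checked in tests). Negative
  components cannot occur; the θ = 0 boundary is compared explicitly.
- **Beta regression** (via `statsmodels` `BetaModel`) uses the
  mean–precision parametrization Beta(μφ, (1−μ)φ) with μ = link⁻¹(β0+β1x)
  and constant φ fitted on the log scale; cloglog, logit and log mean links
  are compared by AIC (k = 3 parameters), ties breaking toward logit.
  Responses at exact 0/1 — which real per-family r values do reach — cannot
  be scored by a beta likelihood; the standard compression
  y′ = (y(n−1)+0.5)/n is applied only when boundary values are present and
  the fit records that it fired. Non-logit links receive link-transformed
  OLS starting values as a fallback; a constant response returns the exact
  degenerate flat fit (slope 0) with a flag instead of a spurious
  convergence failure. The "log" link is implemented as a mean link.
- **Gaussian GLM / ANCOVA**: OLS with t-based p-values; ANCOVA fits
  y ~ population + herkogamy with Type-II marginal F-tests, interaction off
  by default.
- **Pearson correlation** with t on n − 2 df.

No multiple-testing correction is applied across the pairwise association
table; its cells are independent analyses reported side by side.

## The forward simulator

What it emulates: the two-population study design — per population, 30
maternal families (one plant each), 20 genotyped progeny per family, 5 or 6
microsatellite loci with symmetric-Dirichlet allele frequencies; per-flower
herkogamy = population mean + Normal plant effect + Normal flower effect
with 4–6 flowers per plant; family selfing rate = expit(β0 + β1·plant mean
herkogamy) with β1 = −0.15/mm by default (more herkogamous plants self
less — the observed sign, not a mechanism); selfed zygotes culled before
genotyping with probability δ (rejection-sampled, so arrays always reach 20,
mirroring a post-germination sample); per-locus missingness; and a paired
crossing experiment whose self-treatment seed-set and seed-mass means are
each scaled by √(1−δ) so the fitness-product ratio is 1−δ in expectation.

Study presets (`study_config`): the CM-like population uses herkogamy mean
−4.72 mm, sd 5.5 mm with 50.6% among plants, five loci, δ = 0.09, 77 crossing
mothers, and a selfing intercept placing mean s ≈ 0.71; the Map-like
population uses mean +2.57 mm, sd 11.15 mm with 77.3% among plants, six
loci, δ = 0.25, 41 crossing mothers, mean s ≈ 0.32. Adult maternal genotypes
are drawn at F = 0: the per-locus F-model requires F ≥ −p/(1−p) for every
allele, which rare Dirichlet-drawn alleles violate for appreciably negative
F, and no recovery check depends on a negative generating value (the
estimator itself accepts any feasible adult_F and raises a named error
otherwise). Fitness-experiment scale parameters (300 ovules, outcross
seed-set 0.8 with Beta concentration 50, seed mass 15 ± 3 mg drawn Gamma)
are field-plausible choices; none of the published quantities constrain
them, and δ recovery is insensitive to them by construction.

What it does not emulate — and what passing tests therefore do not show:
biparental inbreeding and correlated paternity (every outcross gamete is an
independent pollen-pool draw), pollinator behaviour and spatial pollen
structure, mutation, linkage, family structure in the crossing experiment,
germination/survival fitness components beyond seed-set and mass, or
genotyping error beyond the optional null-allele corruption flag (off by
default). Parameter-recovery results bound estimator error under the model's
own assumptions, not under field realities.

Determinism: identical (config, seed) produce byte-identical serialised
outputs; all pipeline randomness derives from one integer seed.

## Problem sizes used in the checks

The test suite and acceptance script run: 25 random small instances (≤3
loci, ≤10 offspring) against an exhaustive 0.0001-grid likelihood search;
three 30-family recovery experiments with generating s spanning {0, 0.25,
0.5, 0.75, 1}; bootstrap coverage over 100 families at B = 200; δ recovery
with 500 mothers; 50 replicate studies for the r-vs-s bias comparison; 100
beta-regression replicates at n = 500; and 200–1000 replicates of the
29-plant × 5-flower variance-components design. These sizes give the rates
and errors stable Monte-Carlo estimates while keeping a full run in the
tens of seconds on one CPU.

## Known limitations

- Single-locus outcrossing rates, tm − ts, and correlated-paternity
  statistics are not implemented; the package estimates the multilocus rate
  only.
- Null alleles are detected (as mother–offspring mismatches) but not
  modelled in the likelihood; heavy null-allele loads will bias s via
  demoted loci.
- The pollen pool is shared population-wide and fixed per family; a
  family-specific pollen cloud would require correlated-paternity data the
  design does not provide. Per-family estimates from tools that jointly
  re-estimate allele frequencies may therefore differ in small ways.
- The adult-cohort F of a field study is not computable from progeny-only
  genotypes; the package reports progeny-cohort F and says so.
- Bootstrap CIs are percentile intervals; at the s = 0/1 boundaries they
  degenerate with the point estimate, which is reported rather than widened.
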