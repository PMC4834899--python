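# Methods

This note documents the models, algorithms and design choices behind
`poegp`, in the spirit of the methods documentation of packages like
msprime or statsmodels: enough detail to reproduce, audit or extend every
computation.

## 1. Population simulator (`poegp.popsim`)

**Design.** The simulator produces the classical two-phase design used to
evaluate genomic prediction methods: a historical phase that builds
mutation–drift equilibrium and linkage disequilibrium (LD), followed by a
short recorded phase analysed by the models.

* Genome: `n_chrom` chromosomes of `chrom_len` Morgans (default 10 x 1.0).
  SNP positions are uniform per chromosome (default 1000 each); QTL
  positions are uniform genome-wide and are distinct loci, never reusing a
  SNP position (default ~150).  All loci are biallelic with alleles coded
  {1, 2}; allele 1 is the A1 allele counted by the exported indicators.
* Founders: `founder_males + founder_females` individuals (default
  100 + 100) with alleles drawn independently at frequency 0.5 per locus —
  the neutral choice when no founder frequency spectrum is specified, and
  configurable.
* Historical phase: `hist_generations` (default 1000) generations of random
  mating at constant size.  Each offspring draws its sire and its dam
  uniformly with replacement (non-monogamous; selfing impossible because
  sexes are separate).  Mutation flips alleles (1 <-> 2) independently per
  transmitted gamete at 1e-4 per QTL and 1e-2 per SNP by default.
* Recent phase: `recent_generations` (default 3) generations of
  `recent_size` (default 2000) individuals at an exact 1:1 sex ratio, no
  mutation, full pedigree recorded.  Generation 0 of the returned
  population is the last historical generation (parents unknown).
* Recombination: Haldane model — crossover counts per chromosome and
  meiosis are Poisson(map length), positions uniform, no interference; the
  starting parental strand is fair-coin.  Two loci at identical positions
  are never separated.
* Segregating-locus policy: candidate loci are oversampled by a factor
  (default 1.3x) and, at the end of the historical phase, the first
  `snps_per_chrom` segregating SNPs per chromosome and the first `n_qtl`
  segregating QTL are kept.  The realized QTL count can fall short of the
  target when segregating candidates run out, so it varies from run to
  run.  Export additionally drops loci that
  fixed during the recent phase (rare), so exported SNP and QTL sets are
  always polymorphic in the exported generations.

**Implementation.** Meiosis and mutation run in numba kernels; mutation is
realized by geometric gap-skipping over the locus index, which reproduces
the exact per-locus Bernoulli process in O(events) rather than O(loci).
One root seed drives a `SeedSequence` tree (map, founders, one child seed
per generation); the full seed log is stored on the population object and
simulations are bit-reproducible.

## 2. Imprinting overlay (`poegp.imprint`)

Each QTL j carries two allele effects `theta_j1, theta_j2 ~ N(0,
sigma2_qtl)` (default `sigma2_qtl = 1`).  A scenario (rho, s) silences the
maternal copy of a random set MI of QTL and the paternal copy of a random
set PI down to expression level rho, with |MI u PI| the round-half-up of
`s * n_qtl`, split as evenly as possible.  The genotypic value of an
individual is

    sum_NI (theta_m + theta_p) + sum_MI (rho*theta_m + theta_p)
                               + sum_PI (theta_m + rho*theta_p),

computed as the full additive sum minus `(1 - rho)` times the silenced
contributions — algebraically identical, but it makes the rho = 1
phenotypes bit-identical across s, which is both a useful invariant and the
basis for collapsing redundant grid scenarios (a 5 x 4 grid has 17 distinct
phenotype sets).

Phenotypes add an environmental deviation `eps ~ N(0, sigma2_eps)` that is
drawn **once per base population** and reused across all scenarios, so
differences between scenarios are purely genetic.  The absolute trait scale
is not a quantity of interest here (only model comparisons are), so
`sigma2_eps` is calibrated once per base population such that heritability
is `h2 = 0.5`
under the unimprinted (rho = 1) overlay, over all recent-phase individuals
(configurable).  Under complete imprinting of 60% of QTL this yields a
realized heritability of about 0.4, falling with s — the intended
"signal shrinks as imprinting grows" behaviour.

One-locus analytics under Hardy–Weinberg equilibrium, with maternal allele
written first and the maternal copy silenced: the four ordered genotypes
have values `G_11 = (1+rho) theta_1`, `G_21 = rho theta_2 + theta_1`,
`G_12 = rho theta_1 + theta_2`, `G_22 = (1+rho) theta_2` (as deviations
from the mean), giving

    locus_genetic_variance = (1 + rho^2) p q (theta_1 - theta_2)^2
    locus_poe_variance     = 0.5 p q (theta_1 - theta_2)^2 (1 - rho)^2.

At rho = 1 the first reduces to the additive `2 p q alpha^2` and the second
vanishes; their ratio is monotone decreasing in rho.  Both are verified
against brute-force enumeration of the genotype table to 1e-12.

## 3. Pedigree algebra (`poegp.kinship`)

The numerator relationship matrix A uses the tabular method; unknown
parents are unrelated, non-inbred base individuals.  The gametic
relationship matrix L (2n x 2n, rows ordered paternal-then-maternal per
individual) uses the recursion "a gamete received from parent P is the
average of P's two gametes": founder gametes form an identity block, and
the within-individual gamete covariance equals the inbreeding coefficient.
The incidence M maps each individual to its two gamete rows, and
`0.5 M L M' = A` holds exactly — the module's central invariant, checked on
random pedigrees to 1e-12.  Matrices are dense; the intended scale is a few
thousand individuals.

## 4. Bayesian models and Gibbs sampler (`poegp.bayes`)

A model is a list of blocks: flat-prior fixed effects; Gaussian random
effects with an individual-level kernel; and Bayesian-Lasso marker blocks.

* **Marker blocks.** Columns are centered (means stored for prediction);
  `alpha_j | tau2_j, sigma2_e ~ N(0, tau2_j sigma2_e)`,
  `tau2_j ~ Exp(lambda2/2)`, `lambda2 ~ Gamma(shape, rate)`.  Full
  conditionals are the standard Park–Casella set: univariate normal draws
  per coefficient with residual bookkeeping, inverse-Gaussian draws for
  `1/tau2_j` (via numpy's Wald generator), and a Gamma draw for `lambda2`.
  By default one `lambda2` is shared across all marker columns of a model —
  including both parental blocks of the POE model, the minimal reading of a
  single Lasso prior family — with per-block `lambda2` available.
* **Gaussian blocks.** The pedigree additive term (kernel A), the gametic
  term (kernel L through incidence M) and i.i.d. group effects (cage) are
  sampled after collapsing to the individual level: `K_eff = Inc K Inc'`.
  Because every individual contributes one record, the full conditional is
  diagonal in the eigenbasis of `K_eff`, so one update costs two
  matrix–vector products.  This yields the identical posterior for the
  linear predictor and the variance components as sampling the latent
  vector; the individual gametic effects are not separately recovered
  (nothing downstream needs them).  Note `M L M' = 2A` identically, so at
  the likelihood level the gametic term duplicates pedigree-additive
  covariance — a deliberate over-parameterization at the pedigree level
  whose contribution to overfitting is itself a question of interest.
  Eigenvalues below 1e-10 of the maximum are dropped.
* **Variances.** Scaled-inverse-chi-square priors with df = 5 and scale
  `S = var(y_obs) * share * (df + 2) / mean-diagonal-of-kernel`; the
  residual takes share 0.5 and the rest is split equally among non-residual
  terms.  The `lambda2` prior is Gamma(1.1, rate) with the rate set so the
  prior mode equals `2 (1 - R2) * sum_j mean(x_j^2) / R2` for the block's
  share.  The residual update includes the marker ridge terms
  (`sum alpha^2 / tau2`) because the marker prior scales with `sigma2_e`.
* **Missing phenotypes.** Test-set phenotypes are masked and imputed from
  `N(linear predictor, sigma2_e)` every sweep (joint-chain data
  augmentation); the prediction is the posterior mean of the full linear
  predictor, which for Gaussian models equals what post-hoc kernel
  regression would give.  Predictions are invariant to whatever values the
  masked slots contained.
* **Numerics.** Sampling order is fixed (fixed effects, markers, Gaussian
  blocks, tau2/lambda2, variances, masked phenotypes).  Sampled `tau2` and
  variances are floored at 1e-10.  Marker matrices and eigenvector bases
  are held in float32 — the rounded design matrix is *the* design matrix,
  so the algorithm stays exact, and Monte-Carlo noise dwarfs the 1e-7
  relative rounding; residual bookkeeping is float64.  The coefficient
  sweep is a numba kernel; its normal variates are pre-drawn from the
  single numpy Generator, so runs are reproducible given the seed.
* **Default schedule** is 60,000 iterations, 10,000 burn-in, thinning 10
  (5000 retained draws); the desk-scale profile uses 15,000 / 3,000 / 10.

Sampler correctness is established by three oracles: with frozen `tau2` the
posterior mean equals the closed-form ridge solution; an A-kernel-only
model at fixed variances equals mixed-model-equation BLUP; and
simulation-based calibration at toy scale (n = 100, p = 20, 200 replicates
with truth drawn from the prior) recovers nominal 90% credible-interval
coverage.

## 5. Parent-of-origin scan (`poegp.poescan`)

Per marker, OLS of the phenotype on intercept + shared covariates +
maternal indicator + paternal indicator; the test is the two-sided t-test
of the contrast `alpha_f - alpha_m = 0`, i.e. the imprinting deviation of
the one-locus model, not the marginal significance of either parental
effect.  Covariates are projected out once (Frisch–Waugh–Lovell) and the
per-marker 2 x 2 systems are solved in batch with residual df
`n - k - 2`.  Markers whose parental indicators are collinear (no
reciprocal-heterozygote contrast) are excluded with a warning.  Family-wise
error over p markers is controlled at the Šidák threshold
`1 - (1 - alpha)^(1/p)`; membership in the significant set Phi uses strict
inequality.

## 6. Experiment harness (`poegp.pipeline`)

`run_grid` simulates one base population per replicate, overlays every
requested (rho, s) scenario on the same QTL effects and environmental
deviations, fits the requested models with the second recent generation as
training data and the third masked for testing, and records Pearson and
Spearman correlations and MSE on both sets.  Scenarios with rho = 1 are
collapsed to a single run (their phenotypes are identical across s).
Relative superiority is reported as `100 (m_POE - m_ADD) / m_ADD` for
correlations and `100 (MSE_ADD - MSE_POE) / MSE_ADD` for errors, so
positive always favours the POE model.  (Percentage comparisons between
models are ambiguous between percentage points and relative percentages;
the relative reading is the committed convention here.)

Problem sizes: the full design (10 chromosomes x 1000 SNPs, ~150 QTL,
generations of 2000) is used for the single-replicate scan experiment; the
model-comparison grid uses a desk-scale profile of 3 chromosomes x 300
SNPs, 45 QTL, recent generations of 500 and the shorter MCMC schedule, with
3 replicates.  These sizes keep a full grid within minutes on one CPU while
preserving the qualitative structure (LD built by 1000 historical
generations at Ne = 200; several hundred markers per trait; train/test
split by generation).

Within-family cross-validation (for designs with large full-sib families)
assigns a fraction (default 0.5) of every full-sib family to the test set,
keeping at least one member of each multi-member family on each side;
founders and singletons stay in training.  MAF filtering removes markers
with minor allele frequency strictly below the threshold (default 0.05).
Simulated SNPs are exported segregating and are not MAF-filtered before
analysis (the filter exists for real origin-resolved data).

## 7. What the simulations do and do not show

The generator emulates a livestock-style study design: drift-mutation LD, random
mating, biallelic SNPs/QTL, imprinting as parental-copy silencing with a
common rho, environmental noise reused across scenarios.  It does **not**
emulate real-data features such as genotyping error, phasing/parent-
assignment error (origin labels are known by construction), dominance,
maternal environmental effects, selection, or sex chromosomes.  Passing
desk-scale tests therefore demonstrates correctness of the machinery and
the direction of the model comparison, not the magnitude of POE-model
benefits on real data — where phasing error alone can erode the parental
signal.  Two scale effects are worth noting when comparing desk-scale
numbers to full-scale ones: with 500 training records and ~900 markers the
training-set correlations of both models sit near their ceiling, which
compresses the POE model's training-fit advantage (roughly 2% here versus
about 4% at full scale); and with modest absolute test-set correlations,
relative differences between models are noisy across replicates.

## 8. Known limitations

* Dense kinship algebra only (no sparse A-inverse); intended for pedigrees
  up to a few thousand individuals.
* The collapsed Gaussian-block sampler assumes one record per individual in
  the chain (the masked-phenotype design guarantees this); repeated records
  would need the general non-diagonal update.
* Correlated maternal/paternal gametic contributions are not modelled (the
  two parental blocks are independent a priori).
* The scan's OLS test ignores family structure; a kinship-corrected scan is
  out of scope.
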