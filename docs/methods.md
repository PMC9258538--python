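# Methods

`panelgwas` implements a two-stage analysis of multi-environment trials of a
clonally propagated (perennial) diversity panel, followed by genomic
prediction. This note documents the models, the numerical choices, what the
synthetic-data generator does and does not emulate, and the limitations a
user should know about.

## Stage 1: from plot records to genotypic values

Each response variable is modelled at the plot level as

    y_ibt = mu + block_b + year_t + (block:year)_bt + covariates + g_i + (g:y)_it + e_ibt

with `g ~ N(0, sigma2_g I)`, `(g:y) ~ N(0, sigma2_gy I)` and
`e ~ N(0, sigma2_e I)`. Both random terms nest within genotype, so the
marginal covariance is block-diagonal by genotype; the engine exploits this
by grouping genotypes with identical within-genotype year patterns and
precomputing per-pattern sufficient statistics, making a (RE)ML fit O(k²p²)
per likelihood evaluation (k = plots per genotype, p = fixed-effect columns)
— milliseconds even for thousands of plots, which is what makes the
parametric-bootstrap studies affordable. Variance ratios are profiled on the
log scale (Nelder–Mead for two ratios, bounded Brent for one), the residual
variance is profiled analytically, and a second perturbed start is used if
the first fails.

Model selection is backward: random terms first, by likelihood-ratio tests
on ML fits using the boundary-corrected `0.5*chi2_0 + 0.5*chi2_1` mixture
reference; then marginal fixed terms by large-sample Wald chi-square tests
(reported as F = W/q), respecting marginality — an interaction blocks
elimination of its main effects. The genotype term is exempt from
elimination: its eBLUPs are the stage-2 response. The final model is
refitted by ReML. Direct calibration checks (null year effect, null
interaction) put the realized type-I error of both test families at or
slightly below the nominal 5%.

Skewed responses can be natural-log transformed; `auto` mode applies the log
when |sample skewness| > 2 (configurable) and records the decision.

### Heritability

Two broad-sense estimators on a genotype-mean basis:

* `HC2 = sigma2_g / [sigma2_g + sigma2_gy/n_y + sigma2_e/(n_y n_r)]`, with
  `n_y`, `n_r` the arithmetic mean numbers of years and of replicates per
  genotype-year cell (so the formula degrades gracefully under unbalance);
* `HO2 = 1 - mean PEV of eBLUP differences / (2 sigma2_g)` — the
  generalized ("Cullis") heritability based on the average reliability of
  genotype eBLUPs. With independent genotypes this reduces to
  `1 - mean(PEV_ii)/sigma2_g`, where `PEV_ii = sigma2_g (1 - gamma_g 1'C⁻¹1)`
  from the genotype's covariance block; fixed-effect estimation uncertainty
  is ignored (second-order at these panel sizes).

On balanced data the two estimators coincide to ~1e-3, which is itself a
useful internal consistency check. The genotypic coefficient of variation is
`CVg = 100 * sigma_g / |mean response|`. Confidence intervals for all three
come from a parametric bootstrap of the fitted model (default 1000 draws;
percentile method). Simulation at true H² = 0.7 puts the 95% CI coverage at
~90%, within the usual tolerance for percentile intervals of variance-ratio
statistics.

### Spatial diagnostics

Residuals on the field grid are summarized by a binned Matheron
semivariogram (default 15 bins up to half the maximum lag). Four families
are fitted by weighted least squares (weights = sqrt of pair counts):
exponential, spherical, gaussian, and Matérn in Stein's parameterization
with smoothness bounded to nu >= 0.75 — the nu = 0.5 member *is* the
exponential model, so leaving it in the Matérn family would make the family
label meaningless. The best family is the smallest weighted SSE; ordinary
kriging under the best model interpolates the surface (the kriging RHS
excludes the nugget, so a pure-nugget model kriges to the global mean and a
zero-nugget model interpolates exactly). Caveat: on single realizations the
family *label* is only weakly identified — spherical and exponential
variograms nearly coincide over a field-trial lag span — while the curve
shape (origin roughness, effective range, sill) is recovered reliably; the
tests therefore assert shape recovery. WLS was chosen over ML for
determinism and robustness; ML fitting is a possible extension. These are
diagnostics only: no spatial correction is applied to the panel data.

## Stage 2: association

All methods take the stage-1 eBLUPs as response. eBLUPs are preferred over
adjusted means for their shrinkage property.

* **Kinship matrices.** `A = WW'/(2 Σ p(1-p))` (VanRaden) with W centered at
  `2p`; dominance `D` uses the classical orthogonal coding
  `{-2p², 2pq, -2q²}` scaled by `Σ(2pq)²`. Because both estimators assume
  linkage equilibrium, SNPs are greedily LD-pruned at r² = 0.5 first
  (keep-first positional scan within a window; composite r² on unphased
  dosages). Missing genotypes are mean-imputed per SNP.
* **Single-SNP scan.** `eBLUP(g) = 1 mu + x_p beta_p + u + e`,
  `u ~ N(0, sigma2_u A)`. One spectral decomposition of A; variance
  components estimated once by ReML under the null and reused for every SNP
  (EMMAX-style). In the rotated basis each SNP test is weighted least
  squares; Wald p-values against chi²₁; Bonferroni threshold 0.05/P per
  response variable and SNP set. Exact per-SNP ReML is available behind
  `exact=True`; on strong signals the two agree, and the approximation's
  null calibration is verified directly (rejection rate 0.050 on 1.2e5
  pooled structured-null tests, KS distance to uniform 0.002).
* **Stepwise multi-locus.** Forward inclusion of the smallest-p SNP as a
  fixed cofactor, re-estimating variance components each step (ties broken
  by genome order; cofactors collinear with the current model are skipped).
  The path stops when the polygenic heritability ratio drops below 0.01 —
  applied only once at least one cofactor is included, since a lone
  large-effect SNP can leave the *null* polygenic ratio near zero — or at 50
  inclusions. The reported model minimizes the extended BIC
  `-2 logL + k log n + 2 gamma log C(P, k)` with gamma = 1 (configurable).
* **Spike-and-slab.** `beta_p ~ (1-pi0) delta_0 + pi0 N(0, sb²)` fitted by
  fully-factorized coordinate-ascent variational inference (the inner sweep
  is numba-compiled; it is inherently sequential over SNPs). The residual
  and slab variances are updated by empirical Bayes within each fit; an
  outer grid of 20 log-spaced `pi0` values in [1/P, 0.5] is combined by
  importance weights proportional to exp(ELBO). PIPs above 0.80 are
  significant. For one or two orthogonal predictors the factorized
  approximation is exact; the implementation is tested against closed-form
  Bayesian model averaging there, and a monotonicity guard on the bound
  (fatal on decrease when hyperparameters are fixed, where coordinate
  ascent is provably monotone) protects against update bugs.
* **PVE.** GBLUP fit of the eBLUPs on A (optionally plus D) by ReML;
  `PVE = sigma2_a/(sigma2_a + sigma2_d + sigma2_e)`. For an outbred panel in
  near-Hardy-Weinberg proportions D is close to the identity (detected via
  the RMS off-diagonal < 0.1, a size-free criterion), which confounds
  sigma2_d with the residual; the fit then carries an explicit
  identifiability warning rather than failing.

### QTL intervals

Each significant SNP defines the interval `[max(1, pos-h), pos+h]` with h
the LD-decay half-width — estimated as the distance at which the smoothed
(3-bin rolling mean) median pair r² of randomly sampled intra-chromosomal
pairs falls below 0.2, or 50 kb by default when estimation is unavailable or
LD never decays below target. Coordinates are 1-based inclusive everywhere
(VCF/GFF3 convention; BED export converts), so a single-SNP interval has
length `2h+1` = 100,001 bp at the default. Overlapping *or book-ended*
intervals merge (adjacent inclusive coordinates describe a gap-free span),
with configurable scope (per method / per response variable / global), and
a merged interval found by at least 2 methods for a response variable is a
*reliable* QTL. Gene models overlap a QTL if they share at least one base
pair.

## Genomic prediction

* **Ridge / GBLUP** (dense architecture): fitted in the kinship (dual) form
  — required when P >> N — with marker effects backsolved as
  `beta = (sigma2_a/c) W' V⁻¹ (y - mu)`; the primal ridge solution gives
  identical fitted values (tested to 1e-6 relative).
* **Sparse predictor**: the spike-and-slab fit's posterior-mean
  (model-averaged) effects; no PIP thresholding for prediction.
* **Assessment**: repeated k-fold cross-validation (default 5x10, uniform
  random folds, seed recorded) with RMSE, Pearson and Spearman correlations,
  and the regression of observations on predictions (intercept, slope,
  adjusted R²). The "no-bias" test is a joint F-test of intercept = 0 and
  slope = 1 in that regression. GWAS results are never used in training.
  Out-of-population prediction trains on the full panel and predicts an
  external progeny over the intersected marker set (no imputation).
* **Architecture classification**: per trait class, the median and 10%/90%
  quantiles of `corS(sparse) - corS(dense)` across member response
  variables; positive median calls the class sparse, and confidence is high
  when the quantile interval excludes zero.

## The synthetic-data generator

What it emulates: an outbred panel (~280 genotypes by default) with weak
3-group structure (Balding–Nichols drift, Fst = 0.05, frequencies recentred
on the ancestral value so marginal MAF is preserved); SNP panels with block
LD — per gamete, one latent allele per LD block (default 100 kb) copied to
every SNP, then per-SNP "mutation" resampling from the population frequency
(rate 0.15), giving within-block pair r² ≈ (1-m)⁴ and independence across
blocks, with marginal allele frequencies exact by construction; block base
frequencies shared within a block (per-SNP jitter 0.05) so the copy scheme
yields strong local LD. Trials are 5 complete blocks x 2 years with
genotype-year interaction, plot covariates (independent of genotype, as
trial-conduct effects), a field grid, and missingness completely at random.
Genetic values come from a few Normal-effect causal SNPs (sparse) or all
SNPs (dense), rescaled so realized components hit the configured variances;
the default plot-level proportions (0.35 genetic, 0.20 interaction) give a
broad-sense heritability of ~0.71 for the default design, and
`plot_variance_components` solves for proportions that hit any target H².
Magnitudes of block/year/covariate effects are free parameters of trial
conduct (defaults 0.3/0.3/0.15 SD on unit total variance).

What it does not emulate — and hence what passing tests do not show about
real data: coalescent-accurate haplotype structure and long-range LD;
pedigree relatedness; informative (non-random) missingness; epistasis and
dominance at the trait level; genotype-environment structure beyond a
year main effect and iid genotype-year interaction; genotyping error.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the Monte-Carlo studies at
desk scale as the package's own verification budget: e.g. 60 planted-QTL
simulations at N = 300 / P = 5000, 1.2e5 pooled null SNP tests, 100
bootstrap-coverage rounds at 200 bootstrap draws, a 10-replicate battery of
16 traits for the architecture classifier. Estimates quoted in this note
(calibration, coverage, power) are the quantities those runs compute.

## Known limitations

* Stage-1 random structure is fixed to genotype + genotype:year; other
  random terms (e.g. random block) are rejected explicitly.
* Fixed-effect tests use large-sample chi-square references, not
  small-sample Satterthwaite/Kenward-Roger corrections; fine at hundreds of
  plots, conservative-to-exact in our calibration runs.
* The scan's EMMAX approximation slightly underestimates per-SNP variance
  re-estimation effects for very large effects (exact mode available).
* LD pruning is greedy keep-first; no MAF-aware or pairwise-optimal
  pruning.
* The spike-and-slab ELBO can dip by tiny amounts when empirical-Bayes
  hyperparameter updates interleave with coordinate updates (the strict
  monotonicity guard applies when hyperparameters are fixed).
* Out-of-population prediction intersects marker sets; it does not impute.
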