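# Methods

`methalc` implements a blood DNA-methylation analysis of self-reported
alcohol consumption with two statistical cores — a penalized-regression
methylation score (EpiScore) and a Bayesian mixture-prior model for
epigenome-wide association and variance partitioning — plus a synthetic
cohort generator that provides ground truth for testing both. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Phenotype

The consumption phenotype is self-reported alcohol units per week (1 NHS
unit = 8 g / 10 ml ethanol), analysed as `log(units + 1)` (natural log; all
correlation and R² metrics are invariant to the log base). Drinker
categories use 0 units for non-drinkers and sex-specific moderate/heavy
thresholds of 14 (F) and 21 (M) units/week. The thresholds are treated as
inclusive ("14 and over"); the boundary convention is asserted in the test
suite so a change would be caught. Each record carries a "normal week" flag
(normal / more / less / unknown) stating whether last week's intake matched
habit. Records with an unknown flag stay in whole-cohort analyses and are
excluded from flag-stratified subsets.

## EpiScore

Candidate CpG beta values are optionally restricted to a pre-selection list
(prior-evidence CpGs) and/or an array-intersection list, mean-imputed per
CpG, and standardized to mean 0 / SD 1 using training-set parameters.
An elastic net with mixing parameter α = 0.5 is fitted over a λ path;
λ is chosen by seeded k-fold cross-validation (default 10 folds) at the
minimum mean CV squared error — not the 1-SE rule — with ties broken toward
the smallest (densest) λ. Defaults for the path: 50 λ values down to 0.01 of
the null-model λ (the convention for p > n in the standard coordinate-descent
packages); large-scale runs in the test-suite and acceptance script use a
20-point path down to 0.05, which selects mid-path in all observed runs and
cuts fitting time several-fold. Zero-variance CpGs are dropped before
standardization (their z-score is undefined).

Projection multiplies each model CpG's standardized value by its weight and
sums. By default the target cohort's own means/SDs standardize the features
(the way such scores are deployed across cohorts with different
distributions); training-parameter standardization is available as an
option and reproduces the in-sample linear predictor up to the intercept.

Evaluation reports the Pearson correlation between score and log units, and
the incremental R² (percent) from adding the score to a linear model with
age and sex; significance is the marginal Wald test for the score
coefficient in the full model. Incremental R² equals the squared
semi-partial correlation of the score with the outcome given age and sex —
an algebraic identity the tests verify to 1e-8.

The design grid crosses feature sets (all CpGs vs pre-selected) with
training subpopulations (everyone vs normal-week reporters), evaluating each
trained model on the full test set and on each normal-week-flag stratum.
Sex-specific designs train female-specific, male-specific and sex-agnostic
models at matched size min(n_F, n_M) (the agnostic set splits floor/ceil
between sexes) and test each sex under own-sex, opposite-sex and agnostic
modes.

## Mixture-prior EWAS and variance partitioning

For the association model, CpG M-values (logit of beta) and the phenotype
are first residualized on covariates — age, sex, smoking score, plus batch
for the M-values — and standardized; the residual phenotype is scaled to
unit variance. The model is

    y = X β + ε,   ε_i ~ N(0, σ²_ε)
    β_j ~ π₀ δ₀ + Σ_k π_k N(0, γ_k),   k = 1..3

with mixture variances γ = (0.0001, 0.001, 0.01). Because y has unit
variance these are literal fractions of phenotypic variance: the three slabs
describe CpGs explaining 0.01%, 0.1% and 1% of the phenotype. Priors left
open by convention are set to BayesR-family defaults: symmetric
Dirichlet(1,…,1) on (π₀..π₃) and a weakly informative scaled-inverse-χ²
(ν₀ = 2, s₀² = var(y)/2) on σ²_ε; both are configurable.

Sampling is single-site Gibbs with conjugate conditionals and residual-vector
maintenance, so each CpG update costs O(n). Implementation choices that
matter for reproducibility:

* **Update order.** Each sweep visits CpGs in a pseudo-random order keyed by
  a 64-bit hash of (CpG identifier, sweep, seed). Keying the order to
  identifiers rather than column positions makes the chain exactly
  equivariant under column permutation (permuting the input columns permutes
  every posterior summary bit-for-bit), which the tests assert; varying the
  order per sweep avoids order artifacts.
* **Fixed draw consumption.** Every CpG update consumes exactly one uniform
  and one normal draw regardless of the sampled component, so the random
  stream position never depends on the sampled path.
* **Sparse start.** Chains start at β = 0 with mixture proportions
  (0.95, 0.05/K, …), the convention in BayesR-family samplers; a uniform
  start floods the smallest slab on the first sweep, which short burn-ins
  cannot undo.
* **Chain accounting.** Defaults are a burn-in of 5000 sweeps, 10,000
  retained draws thinned by 5, and summaries over the last 1000 stored
  draws (`used_iterations`); all three knobs are independent because the
  stated combination is over-determined (10,000/5 = 2000 stored, of which
  1000 are used).

Summaries per CpG: posterior mean effect (standardized scale), posterior SD,
PIP (fraction of used draws in any nonzero component — membership in a
specific slab is not distinguished), and mixture occupancy fractions. The
variance component per draw is the model-implied fit variance
var(Xβ(t))/var(y), computed in-kernel from the maintained residual; its
posterior mean and equal-tailed 95% credible interval form the
variance-component estimate. The sum-of-squares accounting Σ_j β_j²(t) — the
convention in the variance-partitioning literature — is reported alongside
(`sum_sq_mean`). The two coincide when columns are uncorrelated; under
correlated columns the sum of squares moves with aligned or cancelling
coefficient pairs that leave the fit unchanged, and in planted-truth
experiments only the fit-variance measure recovers the generating value, so
it is the estimate of record here. CpGs with PIP
strictly above 0.95 are called significant. Convergence is checked with a
Geweke z comparing the first 10% and last 50% of a scalar chain, using
batch-means spectral variance estimates (dependency-free and robust to
autocorrelation), plus a lag-k autocorrelation table.

For oracle testing the sampler can freeze σ²_ε and/or π: with one slab and
both frozen it draws from the exact conjugate Normal posterior (ridge
limit), and with one slab and σ²_ε frozen its inclusion probabilities are
comparable to exhaustive 2^p Bayesian model averaging with analytic Gaussian
marginals and the Beta-Binomial subset prior induced by Dirichlet(1,1).

## Association battery

Continuous outcomes: standardized β from OLS of z-scored outcome on z-scored
exposure with age and sex. Binary outcomes: OR per SD from logistic
regression (perfect separation raises instead of returning a silent
estimate). Mortality: HR per SD from a Cox proportional-hazards model.
Brain volumes additionally adjust for intracranial volume. All intervals
are Wald (symmetric on the log scale for OR/HR), matching conventional
reporting. Smoking status, where used as an outcome, is coded ordinally
(never/ex/current). Benjamini–Hochberg FDR is applied across one cohort's
full battery, both exposures jointly (the correction family is a documented
choice; correcting exposures separately is equally defensible). Fewer than
10 complete cases, a single outcome class, or zero events skip the fit with
a warning rather than producing an unstable estimate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, from one integer seed fanned into named substreams (methylome,
effects, phenotype noise, covariates, reporting, split).

**Methylome.** Each CpG is assigned a methylation state — low (40%),
intermediate (20%), high (40%) — with state means −2.5 / 0 / +2.5 on the
M-value (logit) scale, reproducing the familiar bimodal beta distribution.
Per-(batch, CpG) shifts (SD 0.15), two cell-composition-like latent factors
(loading SD 0.15, giving the latent structure a ~10% variance share and
typical inter-CpG correlations around 0.1, in line with post-QC blood
methylomes) and per-CpG noise (SD 0.4–0.8) are added on the M scale and
mapped through the logistic function, so beta values are strictly inside
(0, 1) while all structure is linear in M.

**Phenotype.** Causal CpGs are planted in three tiers whose per-CpG variance
fractions default to 0.0001 / 0.001 / 0.01 — deliberately the same scale the
EWAS mixture prior assumes — with default counts 1000/300/10, which sum to
a methylome-explained fraction of 0.5, in line with the ~45–50% estimates
such variance-partitioning analyses report for this phenotype. Effects act
on the standardized *biological* M component — technical batch shifts exist
only in the measured matrix and never drive the phenotype, since array batch
cannot cause drinking behaviour. Gaussian noise is scaled so the planted score
explains `total_methylome_variance` of the covariate-free phenotype, which
is then scaled to SD 0.8 log units and shifted by intercept 1.7 plus
age/sex/smoking effects (−0.05, +0.35, +0.15 per SD/indicator). These
settings give a weekly-units distribution with mean ≈ 10, a substantial
non-drinker mass (the exp(x)−1 floor at zero), and more male than female
heavy drinkers — the gross features of the cohort tables the analysis is
designed around.

**Reporting.** The methylome tracks *habitual* intake; the questionnaire
records *last week*. Reporters are normal / more / less / unknown with
probabilities 0.628 / 0.225 / 0.097 / remainder; "more" reporters' last-week
units are habitual × (1 + |N(0, 0.5)|), "less" × max(0, 1 − |N(0, 0.5)|).
The joint distribution of habitual and last-week intake is not something the
source cohorts publish; this multiplicative mechanism is a stated stand-in
that realizes the qualitative property downstream analyses rely on — scores
built from the methylome correlate best with reported units among
normal-week reporters.

**What passing tests show.** Recovery and calibration on these cohorts
demonstrate correctness of the estimators under the generator's assumptions:
linear effects on M-values, Gaussian noise, independent samples, missingness
absent or completely at random. Real methylation data adds relatedness,
cell-composition confounding correlated with exposure, probe-level
artefacts, and non-linear dose responses, none of which are generated; test
results quantify implementation correctness, not expected field performance.

## Problem sizes and numerical tolerances in the test-suite

The acceptance-style tests run at deliberately desk-scale sizes: variance
component recovery and null calibration at n = 2000 samples × p = 2000 CpGs
(10 replicates, burn-in 500, 1000 used draws), large-effect detection at the
same size (5 replicates), EpiScore recovery at n = 5000 / p = 5000 with a
60/40 split (5 replicates; the all-CpG elastic net runs under a bounded CV
budget of 5 folds, a 10-point λ path and 40 coordinate-descent iterations,
since an unbounded 10-fold CV at p = 5000 costs ~15 minutes per replicate
on one CPU), reporting-model monotonicity at n = 1200 / p = 600
(10 replicates). Calibration/recovery cohorts for the sampler use exact
reporting (every reporter a "normal week" reporter) so the planted variance
decomposition applies to the phenotype the sampler analyses; reporting
deviations are exercised by the monotonicity experiment. Closed-form comparisons (residualization,
incremental R², BH step-up) are asserted to 1e-10–1e-12; sampler-vs-oracle
comparisons use 3 Monte-Carlo SEs with batch-means variance; parameter
recovery uses 3 Wald SEs.

## Known limitations

* At n = p = 2000 the smallest mixture component (γ = 1e-4) is only weakly
  identified (n·γ = 0.2), so under a pure-noise phenotype the posterior
  variance component does not concentrate at zero: across seeds it centres
  near 0.03 with a right tail reaching ~0.07–0.12 for a minority of
  datasets, a property of the exact posterior (long chains reproduce it),
  not of chain length. At the cohort scale the model is designed for
  (n ≈ 17k, p ≈ 750k) the same component is an order of magnitude better
  identified per CpG. Consequently the null variance component should be
  interpreted against a seed distribution, not a point threshold, at desk
  scale.
* Detection of a CpG explaining 1% of phenotypic variance at n = 2000 sits
  right at the PIP = 0.95 boundary (conditional z ≈ 4.7): realized per-CpG
  signal varies between dataset draws, so converged PIPs for such effects
  spread over roughly 0.3–1.0 and only about half exceed 0.95. This is a
  power statement about the sample size, not a sampler property; reliable
  (>80%) detection of 1% effects needs n ≈ 3000 or more.
* Single chain by default; the Geweke diagnostic and autocorrelation table
  are the convergence evidence. A multi-chain Gelman–Rubin check can be
  layered on by running `gibbs_sample` at several seeds.
* The elastic net is trained on beta values and the EWAS on M-values
  (both configurable); this mirrors standard practice where prediction uses
  the bounded scale and inference the variance-stabilized scale.
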