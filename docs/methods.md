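# Methods

## Model

`mtme` fits a Gaussian linear mixed model to plot × trait observations
from balanced randomized-complete-block trials replicated across
environments.  Writing y_p for the T-vector of trait values on plot p
(genotype i, environment e, block k):

    y_p = β[e,·] + r_{ek} + g_i + u_{ie} + ε_p

with r_{ek} ~ N_T(0, Σr⁽ᵉ⁾), g_i ~ N_T(0, Σg), u_{ie} ~ N_T(0, Σint⁽ᵉ⁾)
and ε_p ~ N_T(0, Σε⁽ᵉ⁾), all mutually independent.  The *null* variant
omits u.  Fixed effects use the cell-means parameterization (one mean
per environment × trait, no intercept or contrasts), which maps
one-to-one onto the reported posterior means of trait averages per
site.

Two structural choices deserve comment, both of which resolve
ambiguities inherent in the textbook "unstructured covariance across
all environment × trait combinations" presentation of MTME models:

* **Genetic effects are main + per-environment deviation.**  An
  unstructured (E·T) × (E·T) genetic covariance is not identifiable
  from two environments with 25 genotypes; the main-effect covariance
  Σg (shared across environments) plus per-environment deviation
  covariances Σint⁽ᵉ⁾ is, and it yields the within-environment genetic
  covariance Σg + Σint⁽ᵉ⁾ that heritability and genetic-correlation
  summaries need.  Under this parameterization the genetic covariance
  between environments is Σg.
* **Block and residual covariances are block-diagonal by environment.**
  Blocks and plots are physically distinct per site, so
  cross-environment block or residual covariances are inestimable and
  are fixed at zero.  Block identity is nested within environment even
  when textual labels repeat across sites.

There is no free-standing random environment effect: with two
environments its variance would be inestimable, and the environment
dimension is already carried by the fixed cell means and the
per-environment covariance structure.

## Priors and standardization

Each covariance matrix has an inverse-Wishart prior IW(ν₀, V₀) with
defaults ν₀ = d + 1 (which makes every marginal prior correlation
uniform on (−1, 1)) and V₀ = 0.05 · I on the *working* scale.  By
default each trait is internally standardized to unit empirical
variance (results are back-transformed), so the default prior scale is
5% of the phenotypic variance per trait.  This is deliberately weaker
than scale choices of order half the phenotypic variance: a block term
has only 3 levels per environment, and a prior located at half the
phenotypic variance overwhelms 3 degrees of freedom entirely — in
probe runs it pushed the block-variance HPD an order of magnitude above
the generating value and propped up interaction variances that were
truly zero.  At 5% the prior remains proper and the data dominate all
terms with ≥ 3 levels.  Fixed effects get independent N(0, 10⁸) priors
on the working scale — effectively flat.

Standardization also buys exact scale equivariance: multiplying one
trait's data by a power of two reproduces bit-identical heritability
and correlation chains, because the working-scale problem is unchanged
(the test suite checks this).  `standardize=False` is available for
conjugate-oracle work where priors must be stated on the data scale;
`PriorSpec.fix_beta` / `fix_residual` pin those parameters at known
values so sampler marginals can be compared against closed-form
posteriors.

## Sampler

One systematic scan per iteration updates, in order: β (per
environment), each random term's level effects (block, genotype, G×E),
each term's covariance, then the per-environment residual covariances.
All full conditionals are exact: Gaussian for β and effects (with
precision c·Σε⁻¹ + Σ_term⁻¹ exploiting balance, so one Cholesky
factorization serves every level of a term), inverse-Wishart for
covariances via Bartlett decomposition.  All randomness flows through
one `numpy.random.Generator` seeded from `RunConfig.seed`; identical
inputs give bit-identical chains.  Retained samples number
⌊(n_iter − burn_in)/thin⌋; the per-iteration conditional deviance
−2 log p(y | β, effects, Σε) is recorded for every retained draw.

The default chain plan (20,000 iterations, 5,000 burn-in, thinning 10)
is sized so that a full two-trait fit of the bundled rice scenario
takes seconds while keeping minimum effective sample sizes in the
hundreds; production analyses can simply raise `n_iter`.

## DIC

`dic()` returns (DIC, p_D) with p_D = mean(D) − D(θ̄) and
DIC = mean(D) + p_D.  By default D is the **marginal** deviance
−2 log N(y; Xβ, V) with V = Σ_k Z_k (I ⊗ Σ_k) Z_kᵀ + R — random effects
integrated out, so θ is (β, covariance matrices).  The conditional
alternative (deviance given the random effects, θ̄ plugging in
posterior-mean effects) is available via `deviance="conditional"`, but
it is not the default for model comparison: with 50 G×E effect levels
the conditional deviance rewards effects that merely absorb plot noise,
and in simulation it produced weak spurious evidence for interaction
(ΔDIC slightly above 2) on roughly half of datasets generated with
*zero* interaction variance.  The marginal version, in the same
experiment, gave ΔDIC ≤ 2 on 10/10 null datasets while exceeding +20 on
10/10 datasets with strong interaction.  The marginal deviance is
evaluated on an evenly spaced subsample of at most 400 retained draws;
at that size its Monte-Carlo error is well under the ±2 decision band.
Model preference follows ΔDIC = DIC(null) − DIC(full): `full` if
ΔDIC > 2, `null` if ΔDIC < −2, otherwise indistinguishable.

## Posterior summaries

* **Heritability** per trait and environment, per iteration:
  h² = σ²g/(σ²g + σ²r + σ²ε), where σ²g is the (main + interaction)
  diagonal under the full model and the main diagonal under the null.
  The same rule supplies the genetic covariance entering the
  **genetic correlation** within each environment.  Samples are bounded
  in [0, 1] and [−1, 1] by construction; iterations with a zero genetic
  variance are excluded from correlation chains with a reported count.
* **Coefficients of variation**: CVg = 100·√(E[σ²g])/ȳ and
  CVe = 100·√(E[σ²ε])/ȳ with ȳ the arithmetic mean of observed values
  for that trait × environment (the point version printed in trial
  reports); their ratio is the relative variation index.
* **Genotype genetic values**: posterior mean of g_i + u_{ie} per
  environment (requires `store_effects=True` for HPD intervals),
  ranked descending with ties broken by label.
* **HPD intervals** use the Chen–Shao empirical method: among all
  windows of ⌈prob·n⌉ consecutive order statistics, the narrowest
  (lowest start index on ties); endpoints are observed samples.
* **Posterior mode**: argmax of a Gaussian KDE (Silverman bandwidth) on
  a fixed 512-point grid over the sample range — deterministic given
  the chain.
* **Geweke z**: means of the first 10% versus last 50% of the chain,
  variances from the spectral density at frequency zero estimated by a
  Yule-Walker AR fit with order selected by AIC (up to 10·log₁₀ n).
* **Effective sample size**: n/(1 + 2Σρ̂_k) with Geyer
  initial-positive-sequence truncation of paired autocorrelation sums.

## Synthetic data

The generator draws directly from the model above, so parameter-recovery
tests compare posteriors against known truth.  The bundled `rice`
scenario uses the design constants of the emulated trial (25 genotypes,
2 environments, 3 blocks, traits GY and FL) and its reported
environment × trait means (4210.91/3901.56 kg/ha; 99.40/76.43 days).
The trial's generating (co)variances are unknowable from the
publication, so the scenario's magnitudes are this package's choices,
fixed once in `RICE_SCENARIO`: genetic, interaction, block and residual
SDs of (180, 90, 60, 150) kg/ha for GY and (3.0, 1.5, 1.0, 2.5) days
for FL, with genetic, interaction and residual cross-trait correlations
of 0.5, 0.3 and 0.2.  These give broad-sense heritabilities ≈ 0.61 for
both traits and a total genetic correlation ≈ 0.46 — mid-range values
typical of advanced variety trials.

What the generator does *not* emulate: missing plots or unbalanced
designs, spatial field trend, non-Gaussian traits, and heterogeneous
genetic covariance across more than two environments.  Tests passing on
this generator therefore certify the estimation machinery under the
model's own assumptions, not robustness to field realities outside
them.

## Numerical notes and limitations

* Conditional precisions are factorized by Cholesky; a non-SPD
  conditional raises an error naming the iteration.  Inverse-Wishart
  draws are symmetrized after inversion to remove representation
  round-off.
* Observation order is fixed (sort by environment, block, genotype,
  trait), making chains reproducible across platforms.
* Degenerate inputs are rejected early: unbalanced tables, < 2
  genotypes, < 2 blocks, zero-variance traits under standardization,
  constant chains in diagnostics, and HPD requests with
  n·(1 − prob) < 1.
* v1 requires complete balance; the validator reports missing cells
  rather than attempting imputation.
* A single chain is run; between-chain diagnostics (Gelman–Rubin) are
  out of scope, matching single-chain practice with Geweke checks.
* With two environments the split between Σg and Σint⁽ᵉ⁾ is informed
  mainly by the cross-environment covariance of genotype means; its
  posterior is correspondingly wide at 25 genotypes, which the HPD
  coverage tests reflect.
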