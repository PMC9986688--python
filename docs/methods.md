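# Methods

## Model

Breast-cancer incidence for individual *i* is modelled as a proportional
hazard on a latent polygenotype,

    λ(t) = λ₀(t) · exp(σ_P(t) x_P(i)),     σ_P²(t) = γ + θ t,

with x_P standard normal in the population and the polygenic variance
linear in age. The defaults γ = 4.86 and θ = −0.06 (log-hazard-ratio²
units and per-year, respectively) come from segregation analysis of
breast-cancer families and force the supported age range to stay below
80 years for positivity; the package default is ages 20–79 inclusive. A
PRS measures a component of the polygenotype,

    x_P = α x_K + √(1−α²) x_R,

with x_K (the standardized PRS) and x_R (the residual polygene)
independent standard normals a priori. The target of every estimator here
is α ∈ [0, 1): α² is the proportion of the polygenic variance the PRS
explains, and σ_K(t) = α√(γ+θt) is the age-specific log-hazard ratio per
SD of the PRS.

Major-gene effects, lifestyle/hormonal risk factors, competing mortality
and birth-cohort-specific incidence are outside the model: the hazard
carries the polygenic term only.

### Discretization

Ages are handled on a yearly integer grid; hazards are piecewise constant
within years and cumulative hazards are yearly sums. Incidence tables
supplied in integer age bands are expanded to yearly resolution by
constant interpolation within bands. The packaged incidence fixture
emulates the magnitude of recent England & Wales female breast-cancer
rates in 5-year bands (per 100,000 person-years).

### Incidence-constrained baseline

λ₀(t) is not free: the population-marginal incidence implied by the model
must reproduce an observed incidence table μ(t). Marginalizing the hazard
over the surviving frailty distribution gives, for each age in ascending
order,

    μ(t) = λ₀(t) · E[e^{σ_P(t)X} S(t|X)] / E[S(t|X)],   X ~ N(0,1),

where S(t|x) uses the already-solved λ₀ below t. Because λ₀(t) factors
out, the solve is a closed-form rearrangement per age — no global
iteration. Both expectations use Gauss–Hermite quadrature (order 30 by
default; all latent-variable integrals in the package share this default,
and doubling the order beyond 24 moves phenotype probabilities by less
than 1e−6 on the packaged rates). Recomputing the marginal incidence from
the solved baseline reproduces the input to machine precision (~1e−16
relative), far inside the 1e−8 tolerance asserted in the tests.

## Estimators

**Transformed-covariate GLM.** Under the rare-disease approximation the
age-specific log-OR per SD of the PRS is σ_K(t) = α√(γ+θt), so status is
regressed (logistic) on S′ = √(γ+θt)·x_K plus covariates (country as
indicators, principal components as continuous); the S′ coefficient is
α_GLM with a Wald 95% CI. Note the transform multiplies by the
age-dependent polygenic SD — that is what makes the coefficient
age-constant and equal to α.

**Retrospective likelihood.** Each record contributes
log[ P(pheno|x_K=z; α) φ(z) / ∫ P(pheno|u; α) φ(u) du ], where for a
control censored at t, P = E_{x_R}[exp(−Λ(t))], and for a case diagnosed
at t, P = E_{x_R}[exp(−Λ(t)) λ(t)] (a density-style contribution at the
diagnosis age; the yearly grid makes this the natural reading).
Conditioning on phenotype means the case-control sampling fractions appear
in both numerator and denominator and cancel, so no ascertainment
correction is needed. The denominator integral over u uses the same
Gauss–Hermite rule as the inner integral over x_R; quadrature weights are
normalized to sum to exactly 1, which makes the α = 0 identity
(log-likelihood = Σ log φ(z_i)) hold to machine precision. α_RL maximizes
the log-likelihood by bounded scalar minimization (absolute tolerance
1e−5 on α, bounds [0, 0.99]); the 95% CI comprises the outermost points
of a 0.001-step grid whose log-likelihood is within χ²₁(0.95)/2 = 1.92 of
the maximum, walked outward from the MLE (the profile is unimodal on all
simulated cohorts we have examined; a maximum within 1e−4 of a bound sets
a warning flag on the result).

**Proportionality calibration.** α_APP = (η/η₀)·α₀ given the target PRS
log-OR per SD η and a reference PRS with known η₀ and α₀. An option
pre-rounds the constant α₀/η₀ (e.g. to 0.887 at 3 decimals for the
313-SNP reference) to match published prediction tables digit-for-digit.
One published row (PRISMA) prints 0.395 where the rounded-constant rule
gives 0.396; this one-unit-in-the-last-digit rounding discrepancy is
inherent to the published table and that row is excluded from the
digit-matching checks.

**Residualization.** Before likelihood analyses the standardized PRS is
regressed (OLS) on country indicators and principal components with an
additive case/control indicator; only the covariate and intercept
contributions are subtracted (the fitted status effect stays in the
residual — removing it would erase the signal being estimated), and the
result is centered at zero overall.

## PRS scoring conventions

Variant keys are GRCh37 strings `chrom_pos_ref_alt`; the effect allele
must be one of the key's two alleles. No liftover or strand-flip detection
is attempted, but a weight whose effect allele is the key's *reference*
allele is scored on 2−dosage (logged). Missing dosages are explicit (NaN /
`NA`), never silently zero; scoring offers `fail` and `mean_impute`
policies — mean imputation is offered as a pragmatic default for sparse
missingness, without any claim that it matches how any published PRS was
computed. Group SDs use denominator n−1; standardization defaults to the
control group, matching the per-1-control-SD convention of published
summary tables.

## Simulator

`simulate_cohort` draws x_K, x_R independent standard normals, assigns a
censor age uniformly from `censor_age_range`, and runs yearly Bernoulli
trials with event probability 1 − exp(−λ(t)) over ages below the censor
age — exact for the piecewise-constant hazard. Affected women become cases
(age = onset age), the rest controls (age = censor age); sampling repeats
until the requested counts fill. Country labels shift the raw PRS mean
only, emulating the observed between-country PRS heterogeneity that is
not reflected in incidence rates. Determinism: one seeded generator per
cohort; PRS columns are stored rounded at 1e−12 so cohorts are
byte-identical across platforms.

The simulated `prs_std` column is the population-scale Z-score (x_K
itself): the generator knows the true reference distribution, and
re-standardizing by the control-sample mean/SD would inject correlated
noise that the retrospective likelihood's z ~ N(0,1) assumption does not
model (empirically it inflates the sampling SD of α̂_RL well beyond the
likelihood SE and breaks CI calibration). Pipelines that emulate
real-data processing — including the country-shift tests — rebuild
`prs_std` from the observed `prs_raw` via control-group standardization
and residualization; with a reference population of realistic size that
step's noise is second-order.

Default study conditions: cohorts of 8,300 cases / 11,700 controls
(n = 20,000 at the case:control ratio of the large European series the
estimators were developed on), true α = 0.44, censor ages uniform on
30–79. The censor range was chosen so the case and control age
distributions overlap with similar means (≈53 and ≈54.5): when the two
groups occupy disjoint age ranges, the age-dependence of σ_P(t) itself
separates cases from controls and confounds the GLM, masking the
index-event-bias direction the model actually implies. Under these
defaults the estimators reproduce the expected pattern (α_GLM ≈ 0.40
below α_RL ≈ 0.44 at true α = 0.44).

The `bcac_like` preset (~16k cases / ~23k controls) instead targets the
mean age at diagnosis of such a series (≈60 years). Within a
uniform-censor design the mean case age is bounded by ≈61 (censoring at
79 for everyone) and cases are structurally younger than controls, so the
diagnosis-age target forces a late censor window (75–79) and the preset's
controls are older than a real series' controls; the two targets cannot
be hit jointly in this generative family.

What the simulator does *not* emulate: genotype-level data (PRS values
are drawn directly, not built from SNPs), family structure, major-gene
carriers, risk-factor covariates, entry-age/left-truncation effects, and
the year-by-year discrete draw means case contributions are
1 − exp(−λ) ≈ λ rather than exact densities (negligible at breast-cancer
incidence magnitudes, ≤0.2% relative for typical risks). Passing
recovery tests therefore demonstrates internal consistency of estimator
and model — not robustness to the mis-specifications real cohorts carry
(ancestry mixture, genotyping error, secular incidence trends).

## Numerical choices and degenerate inputs

- Gauss–Hermite order 30 everywhere; convergence verifiable by doubling.
- Variance positivity: γ + θt ≤ 1e−10 at any supported age is rejected at
  construction; the exactly-degenerate γ = θ = 0 no-polygene limit is
  allowed (the baseline solve then returns the incidence unchanged).
- The retrospective likelihood evaluates phenotype probabilities in
  age-sorted chunks with the residual integral vectorized across
  individuals and quadrature nodes; the denominator is computed once per
  (status, age) stratum. A dense-trapezoid reference integrator in the
  test suite agrees to <1e−6 in total log-likelihood on 50-record cohorts.
- Estimates are finite-sample quantities: a null cohort can give a
  slightly negative α_GLM, and `AlphaEstimate` deliberately stores the raw
  value (with an `in_range` property) rather than clipping into [0, 1).

## Known limitations

- α is assumed age-constant: the model takes the age-specific effects of
  the PRS and the residual polygene to be proportional. Differential age
  effects would need a richer parameterization.
- γ and θ are treated as fixed external inputs, not jointly estimated.
- Calibration parameters estimated in European-ancestry data do not
  transfer to other ancestries (effect sizes and PRS means both differ);
  the package performs no ancestry recalibration.
- Period incidence rates are used for the baseline constraint; cohort
  effects in incidence are ignored.
- The recovery studies in the tests and the acceptance script run at
  reduced replicate counts and cohort sizes (20 × 20,000 and 8 × 8,000
  respectively), chosen as the smallest scales at which the bias,
  coverage and ordering properties are statistically clean.
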