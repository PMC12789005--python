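# Methods

## The model

Ordinal survey answers on a K-point scale are treated as censored
observations of a continuous latent opinion. For a respondent with
latent mean μ and standard deviation σ, the probability of reporting
category k ∈ {1..K} is the normal mass between adjacent thresholds

    p(y = k | μ, σ, θ) = Φ((θ_k − μ)/σ) − Φ((θ_{k−1} − μ)/σ),

with θ_0 = −∞ and θ_K = +∞ as virtual extremes and θ_1 < … < θ_{K−1}
on the latent scale. Treating the answers this way — rather than as
metric scores — avoids the equal-interval assumption that makes naive
averages of Likert codes misleading (category 4 is not "twice" category
2), and lets dispersion and location be estimated separately.

"I don't know" (DK) answers are never an ordinal category. Questions
offering a DK option get a mixture weight δ: the full answer
distribution is (δ, (1−δ)·p₁, …, (1−δ)·p_K). Item non-response (a blank
answer) is a different phenomenon from an explicit DK: blanks are
excluded from the analysis entirely and counted, not modelled.

### Identification

With categories coded 1..K the scale of (μ, σ, θ) is not identified if
all thresholds are free. The package fixes the two extreme thresholds to
the bounds of the response scale, θ_1 = 1.5 and θ_{K−1} = K − 0.5, and
estimates only the interior ones. This is the natural anchoring when
interior thresholds have priors centred at j + 0.5 (the midpoints
between adjacent codes): a μ of 3.0 then reads directly as "the neutral
midpoint of a 5-point scale". Other anchorings (e.g. fixing μ and σ)
would parameterise the same likelihood; results map between them by an
affine transform. For K = 3 no interior threshold remains and both
thresholds are fixed.

### Priors

Defaults, all overridable through `PriorSpec` / `CovariatePriors`
(units: latent-scale points, i.e. category widths):

| parameter | prior | default rationale |
|---|---|---|
| μ | Normal((K+1)/2, K²) | centred at the scale midpoint, sd of K spans the whole scale several times over |
| σ | Uniform(0.01, 10K) | positive, wide; the lower bound keeps the likelihood finite |
| interior θ_j | Normal(j + 0.5, K²) | centred at the equal-spacing midpoints, weakly informative |
| δ | Uniform(0, 1) | no prior information about DK propensity |
| α (covariate model) | Normal((K+1)/2, (10K)²) | effectively flat |
| β (covariate model) | Normal(0, (10K)²) | effectively flat; no prior direction for any effect |

Threshold ordering is enforced by rejection (log-prior −∞ for any
non-increasing vector) rather than by reparameterisation; with only one
or two free interior thresholds this costs a few percent of proposals
and keeps every parameter on its natural scale.

## Group model and country weighting

The rural/urban model gives each group its own (μ_g, σ_g) — and its own
δ_g, since DK propensity plausibly differs between groups — while
sharing one threshold vector, because the answer categories mean the
same thing for everyone. The likelihood is the sum of the two strata's
log-likelihoods; priors are independent and identical across groups, so
the model encodes no prior rural/urban difference.

Panels balanced 50/50 between rural and urban do not resemble any real
country, so country-level answer distributions are produced *after*
fitting: for every posterior draw, the two groups' DK-adjusted category
probability vectors are mixed as w_R·p_rural + (1−w_R)·p_urban with the
country's true rural population share w_R. Because the mixing is linear
and per-draw, the posterior mean of the country vector is exactly the
same convex combination of the group posterior means (a property the
tests assert at 1e−12), while the per-category credible intervals
correctly propagate the joint posterior. The reported country point
estimate is the posterior mean of the mixed vectors; medians are also
exposed, since for skewed category posteriors the two differ slightly.

The urban-minus-rural contrasts (μ_U − μ_R, σ_U − σ_R, δ_U − δ_R) are
summarised from the same joint draws; a 95% equal-tailed credible
interval excluding zero is the package's operational reading of a
credible group difference.

## Covariate model

The latent mean becomes a linear predictor per respondent:

    μ_i = α + β_loc·urban_i + β_sex·male_i + β_age·age_std_i + Σ_l β_l·politics_il

with rural, female and political centre as reference levels and four
politics dummies (extreme left, left, right, extreme right). σ, the
thresholds and δ do not depend on covariates; DK respondents contribute
only to the δ term, so no design row is built for them.

Numerical choices, all recorded in the fit's provenance:

- **Age** enters standardised to sample mean 0 / sd 1 over the fitted
  stratum, which keeps the random-walk sampler's scales comparable
  across coefficients. The report carries both the per-sd coefficient
  and the per-year conversion (divide by the stratum's age sd in years).
- **Missing covariates** (politics "missing") are listwise-deleted with
  a logged count. A stratum whose politics column is entirely missing is
  refused — the politics contrasts would be pure prior.
- **Constant design columns** (e.g. a single-sex stratum) are detected,
  warned about, and flagged `unidentifiable`; their posteriors equal
  their priors and should not be interpreted.

## MCMC engine

The sampler is adaptive random-walk Metropolis-within-Gibbs: each
iteration sweeps the parameter vector one coordinate at a time with
Gaussian proposals. Proposal scales adapt every 50 iterations toward a
0.44 acceptance rate — the one-dimensional optimum — but only during
burn-in, so the post-burn-in kernel is a fixed, valid Metropolis kernel
and the retained draws target the exact posterior. Defaults are 6
chains × 10,000 iterations with 5,000 burn-in, no thinning, and
over-dispersed starts.

Determinism: every chain owns a generator spawned from the config seed
via numpy `SeedSequence`, and chain-start jitter uses a separately
salted stream, so a fixed (seed, data, config) reproduces every draw
bit-for-bit. This is what makes the CLI's run manifests sufficient to
regenerate artifacts byte-identically.

Convergence is assessed with the classic (non-split) Gelman–Rubin
statistic — W the mean within-chain variance, B/n the variance of chain
means, V̂ = ((n−1)/n)W + B/n, R̂ = √(V̂/W) — computed from the retained
draws. Split- and rank-based variants differ in the third decimal on
converged chains (one test cross-checks against arviz); the classic
form is used because its arithmetic is simple enough to verify by hand.
Runs flag any parameter with R̂ > 1.1; with zero within-chain variance
everywhere the statistic is undefined and raised as an explicit error,
never returned as a silent NaN.

Two performance notes. The single-group and group likelihoods are
evaluated from per-category counts — the sufficient statistics — so
their cost is O(K) per evaluation regardless of sample size. The
covariate likelihood is necessarily O(n); it is vectorised through
`scipy.special.ndtr` and caches the linear predictor between the Gibbs
updates that do not touch β. Cells with numerically zero probability
contribute a large finite penalty (floor ≈ −1e300, or a 1e−300 clip in
the covariate path) instead of −∞, so Metropolis steps reject cleanly
rather than producing NaN differences.

## Synthetic surveys

The generator emulates the panel structure the models assume: per
country, exactly balanced rural/urban and female/male strata (quota
sampling, not random assignment — the counts are exact by design), ages
from a normal truncated to [18, 95] (defaults: mean 46, sd 16), politics
categorical with defaults (0.10, 0.25, 0.30, 0.25, 0.10) from extreme
left to extreme right. Answers are drawn exactly by the model's book:
a DK indicator with probability δ, otherwise a latent normal cut at the
thresholds. One shared stream per scenario seed is consumed in a
documented order (demographics, then per question/stratum DK indicators,
then latent values), so a scenario reproduces its dataset exactly.

For covariate truths the age slope is defined per sd of the *truncated*
age distribution (`Demographics.age_moments`), because that is the
population counterpart of the sample standardisation a fit applies.
The residual mismatch between sample and population constants is
O(n^−1/2) — about 1.5% of the slope at n = 2,000, a small fraction of
its posterior sd.

The built-in reference scenario has 23 countries × 500 respondents
(250/250 rural/urban) with four 5-category questions, one carrying a DK
option; latent means vary smoothly across countries around a mildly
supportive average with a 0.1-point urban lead. Its per-country rural
shares are rough public urbanisation figures shipped as synthetic
defaults only — real analyses must supply their own weighting table.

What the generator does **not** emulate — and hence what passing
recovery tests do not establish about real data: correlation of answers
across questions (questions are independent), within-respondent response
styles (acquiescence, extreme responding), informative non-response
(blanks are generated never, DK at random), panel-recruitment selection
effects, and any deviation of true latent opinions from normality. The
tests demonstrate that *if* data follow the assumed process, the
machinery recovers its parameters — not that real surveys follow it.

## Problem sizes used by the tests and acceptance script

Statistical checks run at sizes chosen to give stable verdicts at
desk scale: single-group recovery at n = 5,000 (6 chains × 10,000);
group-model checks at n = 2,000 per group; covariate coverage over 20
replicates at n = 2,000 with 4 chains × 2,500 iterations per fit
(≈ 9,000 retained draws, enough for stable 95% interval endpoints); the
identical-group null coverage in the acceptance script over 10
replicates. Coverage assertions use ≥ 85% against the nominal 95% —
with 20 replicates the binomial sd at p = 0.95 is ≈ 4.9%, so 85% is a
two-sd-plus allowance, not a loosened target. Kolmogorov–Smirnov
equality checks (exchangeability, model nesting) use a 0.05 distance
bound on ≥ 18,000 pooled draws.

## Known limitations

- The random-walk sampler is adequate for these low-dimensional
  posteriors but would mix poorly for hierarchical extensions; the
  engine's contract (any correct kernel, deterministic under seed) is
  designed so a better kernel can replace it without touching models.
- Classic R̂ can miss some non-stationarity that split-R̂ detects; with
  over-dispersed starts and 6 chains this is a minor risk at these
  model sizes.
- Countries are fitted independently; no partial pooling across
  countries is attempted, matching the per-country reporting the
  weighting scheme serves.
- δ is constant within a group (or stratum, in the covariate model):
  DK propensity does not depend on individual covariates.
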