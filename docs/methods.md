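# Methods

## The model

For even-aged stands at full site occupancy, competition-driven mortality
keeps mean tree size and stand density on an upper boundary that is linear
on log–log axes — the self-thinning line

    lnV = a + b lnN,

with `V` the mean stem volume (dm³/tree), `N` the surviving density
(trees/ha), and `b` classically near −3/2 (Yoda's rule). Repeated
measurements of permanent plots are clustered: observations from the same
plot share site, genetics and initial spacing, so a pooled regression
understates uncertainty and confounds between-plot and within-plot
variation. The package fits three hierarchical forms, with plots indexed
by `i`:

- **M1** (varying intercepts): `lnV = (a + u0_i) + b lnN + ε`
- **M2** (varying slopes): `lnV = a + (b + u1_i) lnN + ε`
- **M3** (both, independent): `lnV = (a + u0_i) + (b + u1_i) lnN + ε`

with `u0_i ~ N(0, σ₀²)`, `u1_i ~ N(0, σ₁²)`, `ε ~ N(0, σ²)`. σ₀², σ₁²
measure between-plot variability; σ² the residual within-plot variability.
A pooled form **M0** (no random effects) is included as a baseline and for
closed-form validation. M3 deliberately carries *independent* intercept and
slope deviations — no correlation parameter — matching its conjugate
block structure; a correlated-effects variant is out of scope.

## Data and the self-thinning filter

Input panels are plot × age tables (plot id, nominal planting density,
age, surviving density, mean stem volume). Only plots actually undergoing
self-thinning trace the boundary, so a plot enters the modelling dataset
only if its cumulative mortality — `(planting density − minimum observed
density) / planting density` — **strictly exceeds** 10% (configurable).
Mortality is cumulative since planting, referenced to the nominal planting
density by default (`reference="first"` switches to the first measured
density). Boundary cases at exactly the threshold are excluded.

## Priors

- `b ~ N(−1.52, 0.39)` — informative, elicited by moment-matching a
  normal distribution to published self-thinning slope estimates across
  species (`elicit_slope_prior`, sample mean and n−1 sample variance).
  The second argument is read as a **variance**; a switch
  (`default_priors(b_scale="sd")`) reads it as an SD for sensitivity
  analysis, since compilations print both conventions.
- `a ~ N(0, 1000)` — vague only under the variance reading (as a
  precision, 1000 would pin the intercept), hence variance is the default
  reading throughout.
- Each precision `1/σ₀², 1/σ₁², 1/σ² ~ Gamma(0.001, 0.001)`.

The shipped literature-slope list is a clearly-labelled **synthetic**
stand-in: deterministic draws rescaled so its sample moments reproduce the
elicited prior. Users with a real compilation should pass it to
`elicit_slope_prior` directly.

## Gibbs sampler

All full conditionals are closed-form:

- `(a, b)` jointly bivariate normal given random effects and precisions.
  The pair is updated **as a block**: lnN is far from zero, so `a` and `b`
  are strongly negatively correlated a posteriori and scalar updates mix
  poorly. Predictor centering is not applied, keeping the intercept on the
  natural trees/ha scale.
- Each `u0_i`, `u1_i` univariate normal.
- Each precision `Gamma(prior shape + count/2, prior rate + SS/2)`
  (`precision_conditional` exposes the arithmetic).

Defaults mirror a long production protocol: 250,000 iterations, 50,000
burn-in, thinning 3, 3 chains. Chain 1 starts at the OLS fit; later chains
at OLS ± k·SE with k ~ U(1, 3) per chain. Tests and quick analyses use
5,000/1,000/thin 2. Split-R̂ (via ArviZ) is logged per parameter; values
above 1.1 trigger a warning.

Numerical choices: sampled variances are floored at 1e−12 (occurrences
counted and logged) so a degenerate precision draw cannot collapse the
conditionals; records are sorted canonically (plot, then descending lnN)
before sampling, so posteriors are bit-reproducible under any input record
order given the same seed; per-chain RNG substreams come from
`SeedSequence(seed).spawn`, and the synthetic generator derives per-plot
substreams from `(seed, plot index)` so adding plots never perturbs
existing ones.

## Model evaluation

- **Summaries**: posterior mean, SD, median and 2.5/97.5% quantiles per
  parameter, pooled across chains, quantiles by linear interpolation.
- **DIC** uses the *conditional* deviance — the normal likelihood of lnV
  with the random effects plugged in as parameters (the convention of the
  standard Gibbs-sampling software for hierarchical models):
  `Dbar = E[−2 log p(y|θ)]`, `Dhat = −2 log p(y|θ̄)` at the posterior
  **mean** of every parameter (random effects included; medians are not
  used), `pD = Dbar − Dhat`, `DIC = Dbar + pD`. Smaller is better.
- **RMSE** uses an n−1 divisor: `sqrt(Σ(y−ŷ)²/(n−1))`. Default mode is
  *conditional* (posterior-mean random effect of the observation's plot
  included in ŷ); *marginal* (population line only) is a flag. The
  conditional mode is the one commensurable with how a mixed model is
  actually used for within-sample prediction.
- **Variance partition** reports `100·median(σ_u²)/total` from
  component-wise posterior medians. The default convention takes the
  residual-variance median as the total variation — appropriate here
  because the between component's posterior is heavily right-skewed with a
  median an order of magnitude below the residual one, and it is the
  convention under which the published worked figures (e.g. 0.009 of
  0.031 → 29.03% between) are arithmetic identities. `total="sum"` divides
  by the sum of the two medians instead; both raw medians are always
  available from the summary table.

## Stochastic frontier comparator

The frontier treats the line as an upper production boundary:
`lnV = a + b lnN + v − u`, `v ~ N(0, σ_v²)`, `u ~ |N(0, σ_u²)|`
(normal–half-normal; the exponential variant is out of scope). With
`σ² = σ_u² + σ_v²`, `λ = σ_u/σ_v`, the composed-error log-likelihood

    Σ_j [ ln2 − lnσ + ln φ(ε_j/σ) + ln Φ(−ε_j λ/σ) ]

is maximized over `(a, b, lnσ, lnλ)` by BFGS (Nelder-Mead polish on
precision-loss stops, 5 deterministic jittered restarts on failure),
starting from OLS with the λ start driven by the residual-skewness sign.
Standard errors come from the inverse observed information (central-
difference Hessian).

Degenerate limit: if the residual skew has the wrong (positive) sign, or
the likelihood-ratio statistic for λ > 0 falls below the 10%
chi-bar-squared critical value (1.642) — a boundary test, since λ = 0 sits
on the parameter-space edge — the one-sided component is indistinguishable
from zero and the exact OLS-equivalent fit (λ = 0) is returned with a
warning. This prevents spuriously shifted frontiers on data with no
inefficiency component.

Two RMSE conventions are reported: `rmse` uses conditional-mean
predictions `a + b lnN − σ_u√(2/π)` (mean-zero residuals, commensurable
with the hierarchical models' RMSE) and `rmse_frontier` the raw frontier
line, which is biased high by construction.

## Synthetic stand generator

`generate_panel` emulates the statistical structure the analysis assumes:
plot-level random intercepts/slopes on the log–log line, Gaussian residual
noise on lnV, and survivor counts that decline along a deterministic
concave per-plot mortality schedule (`final·((k+1)/K)^0.7`). Defaults —
10 plots, biennial ages 14–24, planting densities 3,600–6,000 trees/ha,
`a=17`, `b=−1.5`, `sd_u0=0.05`, `sd_u1=0`, `sd_eps=0.18`, final
mortalities 15–35% — are calibration choices that make pooled summaries
resemble a mature subtropical conifer spacing trial, not estimates.
`generate_table1_like` is a 15-plot variant (four planting densities, five
plots with mortality ≤ 10% so the filter demonstrably drops them, ages and
densities and volumes inside 14–26 y / 1,833–8,650 trees/ha / 32.8–251.7
dm³, log-volumes truncated to that volume range as a rare-excursion
guard).

What the generator does **not** emulate: stochastic mortality, growth
trends in volume beyond what density decline induces, temporal
autocorrelation of residuals within a plot, site/climate drivers, or
measurement error in N. Passing tests therefore demonstrate correctness of
the estimators under the assumed hierarchical-normal data-generating
process, not robustness to real-data violations of it — in particular,
real repeated measures are autocorrelated, which none of the fitted forms
model.

## Problem sizes and test design

Tests run the reduced protocol (5,000/1,000/thin 2, 2 chains); the
calibration check uses 50 replicates of the default 10 × 6 panel and
asserts ≥ 90% coverage of the generative slope by the 95% credible
interval; the hierarchical-vs-frontier comparison uses 20 calibrated
15-plot panels. The acceptance script uses 20,000/4,000/thin 3 with 3
chains — long enough that R̂ < 1.05 on these panel sizes while the whole
script stays under half a minute.

## Known limitations

- M3's independent-deviations structure cannot capture intercept–slope
  correlation across plots (near −1 empirically on uncentered lnN).
- DIC is the conditional-focus variant; marginal DIC, WAIC and LOO are not
  implemented.
- The frontier comparator is cross-sectional: panel/time-varying
  inefficiency and heteroscedastic frontiers are out of scope.
- Stem volumes are inputs; no volume equation from diameter/height is
  provided.
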