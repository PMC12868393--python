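# Methods

## The growth model

Body mass of a pregnant female on gestation day `t` (day 0 = estimated
conception, or observed oestrus for known-length pregnancies) is modelled as

```
mass_ij = m0_i + b_pre_i * min(t_ij, k_i) + b_post_i * max(0, t_ij - k_i) + e_ij
e_ij ~ Normal(0, sigma²)
```

for observation `j` of pregnancy `i`. The curve is continuous at the
inflection by construction — one intercept and two slopes — because a jump at
`k` is not identifiable at realistic weighing densities (one record every
2–3 days). Each shape parameter is a linear combination of an intercept,
fixed effects of pregnancy-level covariates, and random deviations:

```
m0_i     = x_i' beta_m0  + u_m0,preg(i)  + u_m0,female(i) + u_m0,season(i)
k_i      = x_i' beta_k   + u_k,preg(i)   + ...
b_pre_i  = beta_pre      + u_pre,preg(i) + ...
b_post_i = x_i' beta_post + u_post,preg(i) + ...
```

Continuous covariates are centred and scaled by their n−1 sample SD computed
on the pregnancy table (covariates are pregnancy-level, so the weighing table
must not weight the standardization); quadratics and interactions are built
from the standardized values. Dominance status is coded with *dominant* as the
reference level and treatment with *unfed* as reference. The gestation-length
covariate of the oestrus-origin model (`model5`) is deliberately left in raw
days: its coefficient on `k` is then the day-shift of the inflection per day
of gestation length, so values above 0.5 read directly as "extension falls
mostly before the inflection" and the pair (beta, 1−beta) is the
phase-decomposition of gestational extension.

Pregnancy-level deviations of the four shape parameters may be correlated;
the correlation matrix is estimated when `correlated_pregnancy_effects` is
set (the default in the `model1`–`model3` presets; both toggles exist because
whether the crossed-effects models retain the correlated block is an open
design choice).

## Priors

Weakly informative defaults, configurable via `GrowthPriors`:

| parameter | prior | rationale |
|---|---|---|
| m0 intercept | Normal(750, 100) g | adult female mass range |
| m0 covariate effects | Normal(0, 50) g | |
| k intercept | Normal(37.5, 15) d on the day scale | mid-gestation, very wide |
| k covariate effects | Normal(0, 10) d per SD | |
| slopes and slope effects | Normal(0, 10) g/day | |
| random-effect SDs | half-Normal(0, 50) | |
| residual sigma | half-Normal(0, 50) g | |
| correlations | Beta-type prior (eta = 2) on canonical partial correlations | mildly favours identity |

The `k` intercept is sampled on an unconstrained scale and mapped into
(0, horizon) by a scaled logistic transform, with the prior placed on the day
scale (Jacobian included), so the population inflection cannot escape the
gestation window while covariate effects on `k` stay additive in days.
Inside the sampler every non-intercept design column is centred at its sample
mean, so intercepts (and their priors, and the logistic window on `k`)
describe a pregnancy with average covariates; retained draws are translated
back to the raw parameterization on expansion. This matters for `model5`,
whose raw gestation-length covariate (~75 d) would otherwise force the raw
`k` intercept far outside the logistic window.
The correlation prior acts on the canonical partial correlations of the
pregnancy-level block (each `(1−r²)^(eta−1)`), which coincides with the LKJ
family for a 2×2 block and closely approximates it for larger blocks.

## Sampling

The posterior is explored with an affine-invariant ensemble sampler (emcee),
collapsed over the Gaussian-linear block: conditional on the changepoint
coefficients, the variance components, the correlation parameters and the
(non-centred) per-pregnancy changepoint deviations, the model is a Bayesian
linear model in all remaining coefficients and linear random effects, whose
marginal likelihood is available in closed form. Pregnancy-level deviations
are marginalized blockwise with a batched Woodbury identity; crossed (female,
season) deviations join the collapsed linear block. Retained draws are
expanded to the full parameter vector by conjugate conditional draws, so the
saved posterior contains every coefficient, SD, correlation and random
deviation.

Defaults: 2 independent ensembles ("chains"), `max(2·dim+2, 16)` walkers,
900 steps with the first third discarded, 500 retained draws per chain.
Split-R-hat and bulk ESS are computed per collapsed parameter (arviz);
summaries refuse to print when any R-hat exceeds 1.05 unless explicitly
overridden. Degenerate regime to know about: if every weighing precedes the
inflection, `b_post` is informed only by its prior and `k` drifts to the end
of the horizon — the diagnostics flag this rather than the likelihood.

With exactly collinear (noise-free) responses the marginal posterior of
`sigma` is improper (the evidence diverges as `sigma → 0`); the samplers
bound `sigma` away from zero by a relative floor, and near-noise-free data
concentrate just above it.

## The synthetic cohort generator

The generator emulates the structure of the field records the models are
designed for; its defaults are the study conditions:

- 381 pregnancies from 135 females; pregnancies allocated uniformly to
  females (each female at least one). Dominance is assigned per female with
  P(dominant) = 0.81, matching the pregnancy-level dominant share in
  expectation; the empirical pattern that dominants contribute *more
  pregnancies each* is not emulated.
- 75-day gestation; weighing counts Normal(31.8, 8.9) rounded (min 12);
  integer weighing days drawn without replacement with at least four per
  25-day trimester, so the inclusion filter passes by construction (the
  irregular-but-dense cadence, about every 57 h, is what matters — field
  logistics are not modelled).
- Curve truth: m0 = 739.70 g, k = 30.83 d, b_pre = −0.26 g/day,
  b_post = 5.20 g/day, litter effect +0.66 g/day per foetus on the
  post-inflection slope (applied centred at the mean litter so intercepts
  describe an average litter). Litter sizes: rounded Normal(3.57, 1.35)
  clipped to 1–7. Default covariate effects: body condition +0.92 d/SD on
  `k`, NDVI +0.14 g/day/SD on `b_post`; all others zero, and covariates are
  simulated independently to maximize identifiability in recovery tests.
- Random effects: pregnancy-level SDs (60 g, 3 d, 0.15, 0.8 g/day) for
  (m0, k, b_pre, b_post); female and season SDs default to zero; the
  pregnancy-level correlation defaults to identity.
- Residual mass noise: 15 g (~2% of a 750 g female, consistent with
  overnight gut-fill variation); the true value is not reported in the
  source data, so tests vary it.
- Known-length pregnancies: a configurable fraction gets an observed
  gestation length Normal(74.71, 2.6) plus covariate effects (group size
  −1.08 d/SD, condition −0.68, NDVI +0.64, temperature quadratic with vertex
  at +1 SD); the inflection shifts by 0.73 d per day of gestation length, so
  73% of gestational extension falls before the inflection. For these
  pregnancies, covariates act on the inflection *through gestation length
  only* (the direct covariate shift on `k` is replaced by the GL-mediated
  one); otherwise the per-day decomposition parameter would be confounded by
  construction and no model could recover 0.73.
- Pups: one row per foetus; emergence mass 110 g at 25 d + 3.55 g per unit
  of per-capita rate + 3.5 g/day of weighing age (ages uniform 12–30 d),
  noise 10 g; telomere T/S 1.20 with a negligible (−0.002) rate effect;
  survival to 90 d and 1 y generated through standardized emergence mass only
  (logit effects 1.06 and 0.67 per SD) — the mediation structure — with an
  optional direct rate effect for sensitivity checks.

What the generator does *not* emulate, and hence what green tests do not
establish about real data: correlated covariates (collinearity between, say,
group size and competition), per-female heterogeneity in weighing cadence,
abortion-censored trajectories, birth-date uncertainty (±0.84 d in the field),
seasonal autocorrelation in NDVI/temperature, and non-Gaussian mass noise
(scale drift, observer effects).

## Downstream analyses

**Cohort QC.** A pregnancy is retained iff each trimester bin [0, 25),
[25, 50), [50, 75] holds at least four weighings; day-75 records count in the
third bin (the boundary convention is unstated in the source and pinned
here — half-open bins never discard a final-day weighing). The mean
inter-weighing interval is defined as 75·24 / (mean weighings per pregnancy).
Conception is back-dated 75 days from birth for full-term pregnancies and 35
days from loss for abortions; the inter-pregnancy interval is the next
back-dated conception minus the previous birth.

**Gestation length.** A Gaussian mixed model of observed gestation length on
standardized litter size, body condition, group size, concurrent pregnancies,
NDVI and temperature (linear + quadratic), with a female random intercept.
Plausibility bounds (70–81 d) warn, never filter. The IPI model regresses the
interval on raw gestation length; a female random intercept is available but
off by default (the data are ~70 intervals from ~40 females — too thin to
insist on it).

**Pup fates.** A simplified extraction fit *excludes litter-size fixed
effects* so that dividing the post-inflection slope by litter size does not
double-count litter size. From its posterior, `n_draws` (default 100) joint
draws of each pregnancy's GWG duration and per-capita rate are taken with
shared draw indices (the joint posterior is respected). Each draw defines one
imputed pup dataset; the outcome models are fitted per dataset and pooled by
equal-weight concatenation of equal numbers of draws — no weighting scheme is
implied by "combining the posteriors", so none is invented. Duration and rate
are standardized within each imputed dataset. Emergence mass at 25 days uses
a linear age adjustment (residual + prediction at age 25); the exact
age-standardization of the original analysis is not public, so the linear
version is a documented stand-in. Survival models use a logit link (the
Bernoulli family's link was unstated; logit is the default everywhere in this
field). The maternal-age quadratic is built on the standardized age.

## Numerical and design choices

- Quantiles everywhere (credible intervals) use linear interpolation between
  order statistics, so interval endpoints are bit-stable given draws.
- pd counts zero draws toward neither sign (fractions are taken among
  non-zero draws; an all-zero posterior reports 0.5). pd bands: < 0.90
  "highly unlikely", 0.90–0.95 "moderate", > 0.95 "high probability of
  existing".
- Effects on the inflection day translate to effects on GWG duration by
  negation; durations are `horizon − k`.
- The litter effect is reported per foetus by dividing the fitted per-SD
  coefficient by the sample SD of litter size.
- Problem sizes in the tests and the acceptance script (60-pregnancy
  recovery cohorts, 10–20-draw imputation sets, 250-pregnancy known-length
  and pup cohorts giving ~900 pups) were chosen as the smallest sizes at
  which the Monte-Carlo error of each check is comfortably below its
  tolerance. In the acceptance-scale extraction fit the pregnancy random
  effects sit on the linear curve parameters only; per-pregnancy changepoint
  deviations are explicit sampler dimensions and are exercised at the
  60-pregnancy scale instead.

## Known limitations

- The ensemble sampler mixes slowly in the correlation parameters of the
  4×4 pregnancy block on small cohorts; correlation estimates need longer
  chains than slope/inflection estimates.
- Bernoulli mixed models sample random deviations explicitly and are
  practical only for modest numbers of group levels.
- Crossed random effects on the inflection day are sampled as explicit
  non-centred deviations, so very large cohorts with `k` random effects are
  the slowest configuration.
- No abortion-censored trajectories, non-Gaussian residual families, or
  multi-changepoint curves; model comparison (LOO/WAIC) is out of scope.
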