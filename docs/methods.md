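# Methods

## The model

`pmfactors` fits a joint Bayesian hierarchical model with two linked
stages.

**Pollutant stage.** Weekly mean log-concentrations of P speciated PM2.5
components at n monitoring stations follow a multivariate dynamic linear
model with spatially varying structure:

    Y_t(s)     = mu_t(s) + Lambda(s) delta_t(s) + eps_t(s)
    delta_t(s) = Gamma(s) delta_{t-1}(s) + w_t(s)

* `mu_t(s)` is a network intercept: `mu0_p` at IMPROVE (rural) monitors and
  `mu0_p + mu1_p` at STN (urban) monitors, reflecting the systematic
  urban/rural difference between the two collection networks.  An annual
  harmonic pair per pollutant is available for seasonality and is off by
  default in fitting (the latent factors absorb most seasonal structure).
* `eps_tp(s) ~ N(0, sigma2_{net(s),p})`: network-specific error variances.
* `Lambda(s)` (P x M, M <= P factors) carries the lower-triangular
  identification: `lambda_pf(s) = 0` for f > p (exact structural zeros),
  `lambda_ff(s) = exp(g_f(s)) > 0` with `g_f ~ GP`, and free GP entries
  elsewhere, so loadings vary smoothly over space.  For M = 1 every
  pollutant loads on the single factor.
* `Gamma(s) = diag(gamma_1(s), ..., gamma_M(s))`, each `gamma_f` a
  truncated Gaussian process confined to (-1, 1) so the weekly factor
  dynamics are stationary at every site.
* innovations `w_tf ~ GP(0, s_w^2 R(phi_w))` are independent across weeks
  and factors but spatially correlated across sites; initial states
  `delta_{f,0} ~ GP(0, s_{d0,f}^2 R(phi_{d0,f}))`.

All spatial priors use the isotropic exponential kernel
`R(d, phi) = exp(-d/phi)` on planar km (equirectangular projection about
the data centroid; a Matern-3/2 alternative is available).  The kernel
family is a modeling choice: monitoring-network fields need continuity,
not differentiability.

**Health stage.** Each pregnancy i contributes two binary outcomes
(cleft palate, cleft lip) through a bivariate probit: latent utilities

    Z_i = beta' x_i + sum_m sum_{l=3..8} w_{lm} delta_{ilm} + eps_i,
    eps_i ~ N(0, Omega),  Y_ij = I(Z_ij > 0),

where `delta_{ilm}` is the value of factor m at mother i's residence in
gestational week l (weeks 3-8, the embryonic window of lip/palate
formation; residential movers contribute week-specific addresses) and the
weekly coefficients `w_{.m}` follow a GP over `|l - l'|` weeks so the
critical-window profile is smooth.  Priors: `beta ~ N(0, I)`,
`w ~ GP(0, R(phi_week))` with `phi_week = 2` weeks by default,
`Omega ~ IW(I_2, 2)`.

A probit with free Omega is identified only up to per-outcome scale;
draws are kept raw and all reporting (summary tables, probabilities,
DIC, coverage checks) rescales by `1/sqrt(Omega_jj)` so `Phi` applies on
the unit-variance scale.  The likelihood is invariant to that rescaling.

## Exposure model and interpolation

Exposures at residences are unobserved and must be interpolated from the
station-level factor field.  Given the station path, the package models
each mother's 6-week exposure vector as conditionally independent across
mothers with closed-form Gaussian moments:

* the mean kriges the initial state and each week's innovation
  `w_t = delta_t - Gamma delta_{t-1}` to her residence(s) and propagates
  them with the kriged (clipped into (-1, 1)) propagation coefficient;
* the covariance accumulates the kriging-residual variances through the
  same AR recursion, including the cross-site conditional correlation for
  movers, so a mother at a station has (numerically) zero exposure
  uncertainty and one far from all monitors reverts to the stationary
  prior.

The sampler's default update (`exposure_mode="joint"`) draws each vector
from its exact Gaussian full conditional given the latent utilities, so
the outcomes inform the imputed exposures and exposure uncertainty
propagates into the weekly-effect estimates.  Two-stage alternatives are
available: `"sample"` draws from the conditional prior (no outcome
feedback) and `"mean"` plugs in the kriged mean.  Calibration studies
showed the pure two-stage draw produces anti-conservative credible
intervals for the probit coefficients when exposure uncertainty is
non-negligible, which motivated the joint default.

Dropping the between-mother correlation of the kriging residual is a
deliberate simplification: it makes the exposure law per-mother and the
z-conditional update a cheap batched 6M-dimensional draw.  The station
field itself — the dominant shared component of exposure — is retained in
full; only the residual interpolation error is treated as mother-specific.
`extract_exposures` / `interpolate_factors` additionally expose the joint
field-level composition draw (kriged initial state and innovations plus
recursion) used for standalone interpolation; its per-mother marginals
coincide with the law above.

The pollutant-stage parameters (factor path, loadings, propagation, GP
hyperparameters) are updated from the panel only — the outcomes do not
feed back into the station field.  This mirrors the two-stage-in-one-
algorithm structure of the underlying method; validation shows the
residual approximation is negligible at realistic effect sizes because
the panel pins the station field far more strongly than ~500 binary
outcomes could.

## The Gibbs sampler

One iteration cycles:

1. **Factor path** by forward-filtering backward-sampling on the stacked
   n*M state with innovation covariance `s_w^2 R(phi_w) (x) I_M`; missing
   panel cells drop out of the update step.  Exact; verified against
   brute-force joint-Gaussian conditioning to < 1e-8.
2. **Propagation fields**: per factor, the truncated-normal full
   conditional (AR likelihood with spatially correlated innovations +
   truncated-GP prior), sampled by 10 coordinate-wise Gibbs sweeps.
3. **Loadings**: free entries by site-block Gaussian conditionals;
   log-diagonal entries by elliptical slice sampling (no tuning
   parameters).
4. **Network means** (bivariate Gaussian conditional per pollutant, the
   STN offset informed by STN cells only) and **error variances**
   (inverse gamma per network x pollutant).
5. **GP hyperparameters**: conjugate IG(2, 1) draws for the innovation,
   initial-state, and loading variances; ranges by discrete-grid Gibbs
   over 10 log-spaced values spanning 0.05-2 x the station-network
   diameter.  The propagation-field hyperparameters stay fixed (variance
   0.25, range at the grid midpoint) because the truncated-GP prior's
   normalizing constant depends on them and a conjugate update would be
   biased; a flag enables the untruncated approximation.
6. **Exposures** from their z-conditional law (above).
7. **Probit block**: latent utilities by coordinate-wise truncated
   normals; `(beta, w)` jointly for both outcomes by one Gaussian draw
   (prior-precision block-diagonal, likelihood precision
   `Omega^{-1} (x) X'X`); `Omega` from `IW(I + sum e e', 2 + N)`.

Defaults follow a long production run: 25,000 total iterations, 5,000
burn-in, thinning 10.  Every example and test in this repository uses far
smaller, documented sizes.  Randomness derives from a single seed through
per-iteration, per-update spawned streams, so runs are bit-reproducible.

Numerical choices: covariance factorizations add relative jitter 1e-8
(escalated only on failure, with a logged warning); correlation algebra
and kriging operators are cached per grid range; truncated draws use
inverse-CDF sampling clipped strictly inside the open interval;
bivariate-normal rectangle probabilities use 96-node Gauss-Legendre
quadrature of the Drezner identity (absolute accuracy ~1e-14; adaptive
quadrature beyond |rho| = 0.95), which is accurate on the probability
scale but not for deep-tail log-probabilities (~1e-26), where absolute
error dominates.

## Model comparison and classification

DIC uses the health-outcome likelihood by default: per-draw deviance
`-2 sum_i log P(y_i | theta)` from bivariate-normal rectangle
probabilities, with `theta_bar` the posterior mean of the rescaled
`(beta, w)`, the exposures, and the outcome correlation (averaged on the
correlation scale to avoid drift of the unidentified variances).  A flag
adds the pollutant likelihood for a total-model criterion.
`classification_sensitivity` is the share of observed defects whose
posterior-predictive marginal probability exceeds 0.5, pooled over both
outcomes.

## Synthetic data

The generator emulates the study's structure on an abstract 800 x 900 km
domain with a denser central study subregion (no real geography):

* 40 monitors (20 in the study box), STN labels biased toward the urban
  study box; measurements every 3-6 days per site, weekly-averaged; one
  pollutant (ammonium) collected only at STN sites; raw records repeat
  the week's value on each sampling day so weekly averaging reproduces
  the panel exactly (within-week measurement variation is not emulated).
* the `study-scale` preset uses the nine speciated components with
  near-duplicate loading rows for (ammonium, nitrate) and (sulfate,
  sulfur) plus small error variances, reproducing the ~0.95+ weekly
  cross-pollutant correlations that motivate factor-based dimension
  reduction; the `toy` preset keeps four components for fast tests.
* default truth: M = 1; innovation variance 1.0, range 150 km; initial
  state variance 2.0, range 150 km; propagation centered at 0.6 (weekly
  persistence); network offset +0.3 at STN; log-scale error variances
  0.06-0.20.  Health truth: Omega correlation 0.51; weekly effects
  peaking at +0.30 (palate, week 6); regression effects at published
  epidemiological magnitudes (age, education, fetal sex, high blood
  pressure, prediabetes, smoking, alcohol), with Table-1-like covariate
  frequencies.
* a case-control cohort of 208 cases / 358 controls by default, obtained
  by oversampling the prospective model (outcome-dependent retention, as
  in a real case-control design — note a prospective probit fit to such a
  sample is biased, which the analysis accepts by design); a prospective
  option keeps the first N subjects regardless of outcome and is used by
  every calibration study.  15% of subjects move once mid-window to a
  distant subregion and contribute week-specific addresses.

What the generator does not emulate: real geography and land-use
gradients, within-week measurement variability, detection limits,
gestational-dating error, and spatially clustered (rather than uniform)
residences.  Passing tests therefore demonstrate the statistical
machinery under the model's own assumptions, not performance on real
monitoring data.

## Validation designs (and what they show)

* **Oracle equivalence**: FFBS smoothed moments and the mean-mode
  interpolation match brute-force conditioning of the full joint Gaussian
  on instances with state dimension <= 12, to < 1e-8.
* **Conjugate-update checks**: inverse-gamma, normal, inverse-Wishart,
  truncated-normal, and truncated-GP draws match their closed-form laws
  (KS distance < 0.02 at 20,000 draws).
* **Geweke joint-distribution test** on a micro study (3 stations, 9
  weeks, 2 pollutants, 20 mothers; 4,000 marginal-conditional draws vs
  6,000 successive-conditional sweeps): all tracked-moment |z| < 4.  The
  panel span is 9 weeks — the smallest allowing a full 6-week gestational
  window with two possible conception weeks.  The test uses a N(0, 4)
  intercept prior: under the diffuse N(0, 100) fitting default the
  intercept/factor-level random walk mixes too slowly for moment
  diagnostics, without exercising different code.  Data regeneration is
  ordered so that every update is tested as an exact (collapsed) Gibbs
  step.
* **Calibrated recovery**, 20 replicates: 10 stations (7 in the study
  box), 36 weeks, 3 pollutants, 400 mothers (prospective).  The truth is
  drawn from the model's own priors (the Cook-Gelman-Rubin design under
  which credible intervals cover at exactly their nominal rate for an
  exact sampler), except the weekly exposure-effect curve, which is held
  at the generator's realistic default — its unit-variance prior yields
  exposure-dominated cohorts unrepresentative of the target study.  The
  N(0, 4) intercept prior is used as in the Geweke design.  1,600
  iterations (500 burn-in).  Pooled 95%-interval coverage of the rescaled
  beta must fall in [0.93, 0.97]; the posterior sign at the week of
  largest |true weekly effect| must match in >= 18/20 replicates.
* **Model-order selection**, 10 replicates: M = 1 data (8 stations, 30
  weeks, 4 pollutants, 150 case-control subjects), fit at M = 1, 2, 3
  with 700 iterations; DIC(1) < DIC(2) < DIC(3) must hold in a majority.
* **Strong-signal classification**: regression truth scaled 3x on a
  prospective cohort of 400; posterior-predictive sensitivity > 0.9.

These sizes are the package's validation designs, chosen so the entire
suite runs on a single CPU in well under half an hour; the same studies
at larger sizes only tighten the Monte Carlo noise.

## Known limitations

* The station-stage cut (outcomes never inform the station field) is a
  structural choice, not an approximation error bound; with very strong
  exposure effects and sparse monitoring it would bias weekly-effect
  estimates toward zero.
* Per-outcome scale identification relies on rescaled reporting; the raw
  chains wander on the unidentified scale, so only rescaled summaries
  should be interpreted.
* The case-control design is analyzed prospectively (no sampling-fraction
  correction), matching the underlying method; absolute probabilities
  from such fits are not population risks.
* M > 1 models are identified only up to the lower-triangular convention;
  comparing loadings across M requires care with factor order.
* The discrete range grid bounds how well GP ranges can be resolved; the
  grid spans 0.05-2 x the network diameter by design.
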