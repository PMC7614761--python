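# Methods

## Model

For one region, standardized thickness y is modeled as

    y_i = x_i' beta + u_{s(i)} + gamma(age_i) + eps_i,   eps_i ~ N(0, sigma^2)

with fixed effects x = (1, age, sex) (age in years, sex coded 1 = male), a
random intercept u_s per site and, in the GP variant, a smooth age trend
gamma drawn from a zero-mean Gaussian process with squared-exponential
kernel k(x, x') = sigma_f^2 exp(-(x-x')^2 / (2 l^2)) over age. Noise is
homoscedastic within a region. The linear hierarchical model (HBLM) sets
gamma = 0; the site-blind linear model (BLM) additionally drops Zu and is
the second stage of all two-stage pipelines.

Priors (chosen for standardized response scales, weak enough to be
data-dominated at n >= 100):

* beta_j ~ N(0, 5^2)
* u_s | sigma_u ~ N(0, sigma_u^2), sigma_u^2 ~ InverseGamma(2, 2) — the
  partial-pooling structure: small sites are shrunk toward the shared mean
  more strongly than large ones
* sigma ~ HalfNormal(2.5)
* sigma_f ~ HalfNormal(1), l ~ Uniform(1, 8) years

A note on the site prior: an inverse-gamma placed directly on u_s would
exclude the negative offsets real sites exhibit, so the inverse-gamma is the
hyperprior of the offset *variance*, the standard hierarchical construction.

## Inference

Posteriors are sampled with the affine-invariant ensemble sampler (emcee),
32 walkers, positive scales on the log scale with Jacobians included. The
GP latent function is never sampled directly during fitting: it is
marginalized analytically, y ~ N(X beta + Z u, K + sigma^2 I), so the
walkers move only through (beta, u, sigma, sigma_u, sigma_f, l). This keeps
the dimension at ~13 and sidesteps the severe ill-conditioning of the SE
kernel. Each likelihood evaluation costs one dense Cholesky (O(n^3)), which
is why the GP variant is intended for cohorts of a few hundred subjects.

Walkers are initialized in a small ball around the OLS solution. Library
defaults are 800 warmup + 800 retained steps with thinning 3 (GP variant
400/400, thinning 2); the test suite and the acceptance script use reduced
settings (400/400, no thinning; GP 200-300 per phase), which are sufficient
for posterior means and sds at the cohort sizes used. For convergence
reporting the walkers are grouped into 4 pseudo-chains; split-R-hat across
interacting walkers is approximate but a useful screen, bulk ESS is the
standard (arviz) estimator, and since ensemble moves have no divergences the
report carries the mean acceptance fraction instead. Verdicts are pass/warn
at R-hat <= 1.01 and ESS >= 400; reduced-setting fits routinely carry the
warning, which is attached to the fitted model rather than raised.

## Prediction and deviation scores

Per retained draw (subsampled to 200 for prediction), f* = X* beta + Z* u;
for the GP model gamma* is additionally drawn from its exact Gaussian
conditional given the data and that draw's parameters (the train/test joint
covariance conditional), so the across-draw spread of f* carries the full
latent-trend uncertainty. The predictive summary is

* mean f-hat (across-draw mean),
* epistemic variance sigma*^2 (across-draw variance),
* noise variance sigma^2 (posterior mean),

and deviations are z = (y - f-hat)/sqrt(sigma^2 + sigma*^2), atypical at
|z| > 1.96. A closed-form oracle (`gp_conditional_exact`, the standard GP
conditional mean and variance at fixed hyperparameters) and an independent
latent-function MCMC route (`sample_gp_latent`, whitened coordinates) exist
solely to cross-check the sampled predictions; the tests verify agreement
within Monte Carlo error.

## Preprocessing

* Outlier rule: hemisphere-level values more than 2 IQRs from the
  all-subjects mean per (region, hemisphere) are set missing, before
  hemisphere averaging and pooling control+clinical subjects. Quartiles use
  linear interpolation (numpy default). The rule targets impossible values,
  not distributional tails; it is single-pass and deliberately not
  idempotent (re-application can remove more as the stats tighten). Strata
  with fewer than 4 values pass through with a warning flag.
* Hemisphere averaging: mean of available hemispheres; one missing, use the
  other; both missing, missing.
* Split: stratified 70/30 on site x sex x age-quartile (quartiles from the
  full table). Within each site, strata get the floor of their exact train
  share and remaining slots go to the largest fractional remainders, so the
  per-site train share is within one subject of the target; singleton
  strata go to training and are logged.
* Standardization: per-region location (train mean) and scale (train sample
  sd, n-1); test tables always reuse training parameters.
* Model fitting drops subjects missing that region's value, per region
  independently.

## Harmonization baselines

Residualization removes per-region site means (OLS on site indicators) and
restores the training grand mean so values stay in mm. ComBat is the
parametric empirical-Bayes location/scale method pooling across the region
set: location model by least squares (site indicators plus any preserved
covariates), standardization by pooled residual variance (1/n), per-site
location/scale EB-shrunk under a normal/inverse-gamma prior with
method-of-moments hyperparameters across regions, fixed-point iteration to
1e-4 (cap 100), then back-transformation restoring pooled scale, grand mean
and preserved covariate effects. The implementation reproduces Bioconductor
`sva::ComBat` to ~1e-8 on shared inputs (tested via Rscript). Both
transformers are fit on training controls only and applied to test data
with stored parameters — the leakage-safe convention; sites with a single
subject shrink fully to the prior mode with a warning. Nonparametric EB,
ComBat-GAM and longitudinal variants are out of scope.

## Evaluation

rho, SRMSE (= RMSE / mean(y), hence computed on the mm scale; the
coefficient-of-variation convention), EV = 1 - var(resid)/var(y), pointwise
log-likelihood (per-point mean Gaussian log-density, standardized scale),
MSLL (log-loss minus that of the train-mean/train-variance predictor;
exactly 0 for the trivial predictor, negative is better), and
predictive-variance retention var(pred)/var(obs) in percent — the
denominator is always the *raw* test-set variance, which is what exposes
the shrinkage of two-stage predictions. Mean-accuracy metrics compare
predictions with the values the model was trained to predict (harmonized
thickness for two-stage pipelines). No multiple-testing correction is
applied across regions by default (per-region reporting); diagnostics
helpers accept a Bonferroni flag-equivalent by adjusting the threshold.
Site ANOVA uses sum-to-zero contrasts with optional covariate adjustment
(type-II F), Bartlett's test runs on residuals from a stated covariate
regression.

## Synthetic cohorts

The generator mirrors the model: per site, ages uniform in a site-specific
window, ~80% male, additive per-(site, region) offsets (given or drawn
N(0, tau^2)), multiplicative per-site noise scales, shared linear age slope
and sex offset, optional smooth GP age trend realized once per region on a
dense grid (jitter 1e-8) and interpolated, and an optional clinical overlay
adding a fixed shift to selected regions for a flagged fraction of
subjects. The reference configuration — 6 sites x 100 subjects, staggered
age windows spanning 6-40 years, male fraction 0.8, offset sd 0.2 mm, noise
sd 0.15 mm, slope -0.02 mm/yr, intercept 3.0 mm, unit scales, no GP term —
is a draw from the HBLM's own generative process and is the cohort on which
calibration is asserted. `confounded_config` adds site scales 0.8-1.25 for
the harmonization comparisons; `abide_like_config` reproduces the scale of
large pooled releases (20 sites, 13-105 subjects each, 34+1 regions).

What the generator does not emulate — cross-region residual correlation,
within-site scanner drift, non-Gaussian tails, genuine nonlinear
site-by-covariate interactions — bounds what passing tests show: they
validate the estimators under their own assumptions and the qualitative
pipeline ordering under confounding, not performance on any real cohort.

## Numerical choices and edge cases

* Kernel jitter 1e-8 on every diagonal before factorization; non-PD after
  jitter raises.
* The latent-MCMC cross-check samples whitened coordinates (gamma = L xi);
  the direct parameterization is numerically unusable for SE kernels.
* Ensemble seeding: emcee accepts a RandomState state tuple only; the
  wrapper derives it from the integer seed, making fits bit-reproducible.
  Per-region seeds derive from the pipeline seed by a fixed affine rule
  modulo 2^31 - 1.
* Zero predictive variance with a nonzero residual is an error; with a zero
  residual the z-score is 0.
* Degenerate IQR (constant bulk) makes the outlier rule remove every value
  differing from the mean — the documented, if blunt, consequence of the
  "iff |x - mean| > 2 IQR" rule.
* Unknown site labels at transform/predict time raise everywhere: transfer
  to unseen sites (informative-prior re-use) is explicitly out of scope, as
  are cross-region joint modeling and variational approximations.

## Problem sizes

The suite fits on cohorts of 300-600 subjects with reduced sampler
settings; the nested-model check (GP amplitude 0) uses the full n=600
reference cohort because the GP amplitude posterior only concentrates
enough for the 0.05-sd agreement bound at a few hundred training subjects.
Parameter-recovery coverage is asserted over 20 seeds (credible-interval
coverage over 25 seeds for the site-blind model), and the pipeline-ordering
property over 10 seeds with a >= 8/10 majority criterion.
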