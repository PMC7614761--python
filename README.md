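# sitenorm

Normative modeling of multi-site brain morphometry with site as a random
effect.

## The problem

Normative models are the growth charts of neuroimaging: regress a measure
such as regional cortical thickness on reference covariates (age, sex), and
express each person as a deviation z-score against the predictive
distribution. Large cohorts are usually pooled across acquisition sites, and
sites differ systematically — in mean, in variance — for non-biological
reasons. Worse, site is often *confounded* with the covariates of interest
(each site scans its own age range), so the common two-stage recipe —
"harmonize the data for site, then fit a normative model" — can silently
remove biological variance along with the scanner signal.

`sitenorm` implements the single-stage alternative: keep the data untouched
and model site inside the regression as a partially pooled random intercept,

```
y_i = x_i' β + u_{s(i)} + γ(age_i) + ε_i,      ε_i ~ N(0, σ²)
u_s | σ_u ~ N(0, σ_u²),   σ_u² ~ InvGamma(2, 2)
γ ~ GP(0, k),   k(x, x') = σ_f² exp(−(x−x')² / 2ℓ²)   (optional)
```

with x = (1, age, sex). Three estimators are provided, all
scikit-learn-style (`fit(X, y)` / `predict_dist(X)`):

| class | model |
|---|---|
| `BayesianLinearModel` | f = Xβ, site-blind (the second stage of two-stage pipelines) |
| `HierarchicalBayesianLinearModel` | + partially pooled site intercepts (HBLM) |
| `HierarchicalBayesianGPModel` | + squared-exponential GP age trend (HBGPM) |

Posteriors are drawn by ensemble MCMC; predictions carry epistemic variance
σ*² (across-draw spread of f*, including the GP conditional) and noise
variance σ², and deviations are scored as

```
z_i = (y_i − f̂_i) / sqrt(σ² + σ*_i²),        |z| > 1.96 ⇒ atypical.
```

The two-stage baselines are included as transformers — `SiteResidualizer`
(OLS on site indicators) and `ComBatHarmonizer` (parametric empirical-Bayes
location/scale harmonization, optionally preserving age and sex effects;
verified against Bioconductor `sva::ComBat`) — together with the full metric
battery (Pearson ρ, SRMSE, explained variance, pointwise log-likelihood,
MSLL, predictive-variance retention), residual-site-effect diagnostics
(site ANOVA with sum contrasts, Bartlett's test) and a synthetic multi-site
cohort generator with controllable site–age confounding.

## Worked example

```python
from sitenorm import (simulate_cohort, confounded_config, stratified_split,
                      benchmark)

table, truth = simulate_cohort(confounded_config(seed=11))   # 6 sites, n=600
split = stratified_split(table, seed=11)                     # 70/30, site x sex x age
out = benchmark(split.train, split.test, seed=11,
                pipelines=("hblm", "raw", "residuals", "combat",
                           "combat_preserve"),
                regions=table.regions[:3],
                sampler=dict(draws=400, warmup=400, thin=1))
print(out["summary"].round(3))
```

prints (seed 11):

```
                   rho  srmse     ev     ll   msll  variance_retention
pipeline
hblm             0.917  0.056  0.840 -0.533 -0.907              78.748
raw              0.493  0.113  0.316 -1.198 -0.242              30.255
residuals        0.332  0.060  0.109 -1.330 -0.055               1.949
combat           0.334  0.059  0.109 -1.331 -0.056               1.989
combat_preserve  0.754  0.056  0.568 -0.999 -0.411              20.550
```

Read it row-wise: the single-stage hierarchical model (hblm) predicts
held-out thickness best on every metric and its predictions retain ~79% of
the true test-set variance. Residualizing site or applying plain ComBat
before modeling destroys the age signal that the staggered site age-windows
carry (EV ≈ 0.11, retention ≈ 2% — the models collapse toward predicting
the mean); ComBat that explicitly preserves age and sex recovers part of it
(EV ≈ 0.57, retention ≈ 21%) but still trails the hierarchical model. A
negative MSLL means a model beats the trivial train-mean predictor; only the
hierarchical and covariate-preserving pipelines manage it here.

The same stages are scriptable from the shell:

```bash
sitenorm simulate --seed 5 --out runs/sim
sitenorm fit --data runs/sim/cohort.csv --model hblm --fast --seed 5 --out runs/fit
sitenorm benchmark --data runs/sim/cohort.csv --fast --seed 5 --out runs/bm
```

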