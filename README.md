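# allobayes

Bayesian estimation of allometric tree-biomass equations, built for
forest biometricians who need per-component biomass models (stem,
branch, foliage, root, total) from small destructive samples.

Destructive biomass sampling is expensive, so calibration datasets are
typically a few dozen trees. `allobayes` fits the standard allometry

```
ln W = α + b · ln(D²H) + e,    e ~ N(0, σ²)
```

(W dry biomass in kg, D diameter at breast height in cm, H total height
in m) three ways and compares them:

- **Informative Bayes** — a bivariate-normal prior on (α, b) elicited
  from a compilation of published allometric equations for the same
  species and predictor form (sample mean and unbiased covariance of
  the published coefficient pairs, which are strongly negatively
  correlated), with a scalar inverse-Wishart prior (V = 1, v = 0.001,
  i.e. InvGamma(v/2, vV/2)) on σ². Fitting is by a from-scratch Gibbs
  sampler with exact conjugate full conditionals: (α, b) | σ² jointly
  normal, σ² | (α, b) inverse-gamma. Defaults: 25 000 iterations,
  burn-in 5 000, thinning 3.
- **Non-informative Bayes** — the same sampler under independent
  N(0, 1000) priors on α and b; posterior numerically reproduces least
  squares.
- **Least squares (MLS)** — the classical baseline with t-based
  confidence intervals.

Fits are compared on the measurement (kg) scale via mean deviation
(MD), mean absolute deviation (MAD) and root mean squared error
(RMSE), and totals predicted by summing the four component models (AT)
are checked against a directly fitted total model (DT). A synthetic-data
module generates age-cohort-structured tree samples and literature
compilations with the statistical structure the analysis assumes, so
the whole workflow is testable end to end.

## Worked example

```python
import json
import allobayes as ab

# a synthetic 39-tree destructive sample (three age cohorts) and a
# synthetic 32-equation literature compilation for the stem component
trees = ab.generate_trees(ab.TreeSimConfig(n_trees=39, seed=1))
lit = ab.generate_literature(ab.LitSimConfig(n_equations=32, seed=2))

prior = ab.fit_bivariate_prior(lit, "stem")
print(prior.mu.round(4), round(ab.prior_correlation(prior), 3))
# [-3.9257  0.9375] -0.921

data = ab.to_log_data(trees, "stem")
draws = ab.gibbs_sample(data, prior, ab.McmcConfig(seed=3))
print(json.dumps(ab.summarize(draws, component="stem").to_dict(), indent=2))
```

prints (abridged)

```
"alpha": {"estimate": -4.1262, "lower": -4.5038, "upper": -3.7550}
"b":     {"estimate":  0.9749, "lower":  0.9279, "upper":  1.0221}
"sigma2": 0.0312
```

The prior elicited from the 32 synthetic publications is centred near
(−3.93, 0.94) with correlation −0.92: published intercept/slope pairs
trade off against each other, and the elicited covariance carries that
into the posterior. The posterior slope 0.975 with 95% credible
interval (0.928, 1.022) sits close to the least-squares fit
(α = −4.1501, b = 0.9781) because 39 trees already carry substantial
information; the informative interval is the narrower one.
`ab.convergence_diagnostics(draws)` reports effective sample sizes
around 6 500 of the 6 667 retained draws and no Geweke flags.

The same workflow runs from the shell:

```
allobayes simulate --n-trees 39 --seed 1 --trees-out trees.csv --equations-out eqs.csv
allobayes run trees.csv eqs.csv --out-dir results/
```

which writes `fits.json` (5 components × 3 methods), `evaluation.csv`
(MD/MAD/RMSE per fit), `additivity.json` (AT-vs-DT agreement) and a
`manifest.json` from which `run` can be reproduced exactly.

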