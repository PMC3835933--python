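# Methods

## Model

Per biomass component (stem, branch, foliage, root, total), tree dry
mass W (kg) is related to diameter at breast height D (cm) and total
height H (m) through the power-law allometry W = exp(α) · (D²H)^b,
fitted on the log scale:

    y_i = α + b x_i + e_i,   x_i = ln(D_i² H_i),  y_i = ln W_i,
    e_i ~ N(0, σ²)  iid.

The log transform linearises the power law and stabilises the variance
of raw biomass, which grows with tree size. Units are fixed (cm/m/kg)
and never converted or auto-detected; component labels are a closed
vocabulary. The two-predictor form W = a D^b H^c is deliberately not
implemented.

## Priors

**Informative.** (α, b) ~ N₂(μ_b, Σ_b) with μ_b the sample mean and
Σ_b the unbiased (n−1 denominator) sample covariance of coefficient
pairs from published equations of the same form for the same species.
n−1 matters here because literature compilations are small (a few
dozen equations); at least three pairs are required so the covariance
has positive degrees of freedom, and a collinear/identical set is
rejected rather than regularised. Published (α, b) pairs are strongly
negatively correlated — a steeper slope pairs with a lower intercept —
and the elicited Σ_b carries that correlation into the posterior.

**Non-informative.** α ~ N(0, 1000), b ~ N(0, 1000), independent. Over
the plausible slope range (0–1.5) this prior is flat to within a few
parts in 10⁴, so the posterior is essentially the likelihood and the
fit reproduces least squares.

**Residual variance.** σ² carries a scalar inverse-Wishart(V = 1,
v = 0.001) prior in both cases, read as InvGamma(v/2, v·V/2) — the
standard one-dimensional interpretation of scalar (V, v). With
v = 0.001 the prior is essentially flat in ln σ² and contributes
negligible information.

## Gibbs sampler

Both full conditionals are exact:

    (α, b) | σ², y ~ N₂(m, P⁻¹),  P = Σ_b⁻¹ + XᵀX/σ²,
                     m = P⁻¹(Σ_b⁻¹ μ_b + Xᵀy/σ²)
    σ² | α, b, y   ~ InvGamma((v + n)/2, (v V + RSS)/2)

with X = [1, x] and RSS the residual sum of squares at the current
coefficients. The coefficient block is updated jointly (exact for this
model, and it removes the α–b random-walk autocorrelation that
scalar-at-a-time updates would induce). The chain starts at the
least-squares solution — the model is near-conjugate, so this is
effectively an overdispersed-free start and burn-in is cheap
insurance. Defaults: 25 000 iterations, burn-in 5 000 (20%, a
conventional choice; the protocol the defaults follow states no
burn-in), thinning 3. All draws flow from one seeded
`numpy.random.Generator`; identical seed, data and config give
bitwise-identical chains.

`gibbs_sample(..., fixed_sigma2=...)` holds σ² fixed, making the
coefficient draws iid from the closed-form conjugate posterior; the
analytic target (`conjugate_posterior`) is computed independently of
the sampling path and is the primary correctness oracle.

Point estimates are posterior means with equal-tailed quantile
intervals (numpy's linear-interpolation quantile convention).
Posterior means match the convention of common MCMC GLMM software;
equal-tailed intervals (rather than HPD) are directly comparable to
the t-based confidence intervals of the least-squares baseline.
Diagnostics report autocorrelation-based effective sample size
(via arviz) and a Geweke z comparing the first 10% and last 50% of the
chain, with segment standard errors deflated by each segment's ESS;
|z| > 2 or a degenerate (constant) chain is flagged.

## Least-squares baseline

Simple-regression OLS (via statsmodels) with σ̂² = RSS/(n−2) and
t-based intervals — appropriate because destructive samples are small
(tens of trees, cohorts down to single digits). No weighted or robust
variants: the log transform is the heteroscedasticity treatment.

## Evaluation

MD, MAD and RMSE are computed on back-transformed (kg-scale)
predictions with the point estimates plugged into the allometry. The
sign convention is MD = mean(observed − predicted), so positive MD
means under-prediction. Evaluation is in-sample by default, matching
how small destructive studies report fit statistics; predictions use
the plug-in point estimates rather than posterior-predictive draws,
matching how single-number published coefficients are used in
practice. The naive back-transform exp(α̂ + b̂x) estimates the
conditional median; the Baskerville correction (multiply by
exp(σ²/2), available via `correction="baskerville"`) targets the
conditional mean but is off by default, since plug-in back-transformed
coefficients are the dominant reporting convention and kg-scale
evaluation of both is supported either way. RMSE² = MD² + Var(dev)
holds exactly for every call and is asserted in tests.

**Additivity.** AT (sum of the four component-model predictions) is
compared with DT (direct total-model prediction) per tree, reporting
their Pearson correlation and the mean and relative bias of AT − DT.
Because the sum of four power laws with different exponents is not
itself a power law, AT and DT need not coincide even with perfect
component fits; on realistic parameter sets the discrepancy is well
under the fitting noise (correlation > 0.99, relative bias < 5% in the
validation experiments).

## Synthetic data generator

Emulates a stratified destructive sample: three plantation age cohorts
(7, 16, 28 years; 9/14/16 of 39 trees by default) with fixed D and H
ranges per cohort. Diameters are uniform within the cohort range;
ln H follows the log-linear trend through the cohort's (D, H) range
endpoints plus N(0, hd_noise²) noise (default hd_noise = 0.05),
clipped to the height range. This H|D model is a generator choice —
the emulated study design implies no particular height model — chosen
as the simplest mechanism reproducing the cohort marginals.

Per component, W = exp(α + b·ln(D²H) + ε) with ε ~ N(0, σ²); default
(α, b) are published-compilation means per component and σ = 0.2 on
the log scale, a typical residual spread for conifer biomass
allometries. The total is the **exact** component sum, so additivity
holds in truth and any AT/DT slippage downstream is attributable to
the fitted models. Per-component random streams are keyed
sub-streams of the base seed, so adding a component never perturbs
another's draws.

The literature generator draws (α, b) pairs from a bivariate normal
with default mean (−3.8205, 0.9270), standard deviations (0.8, 0.08)
and correlation −0.9 (the correlation is constrained non-positive).

What the generator does **not** emulate: measurement error in D and H,
non-lognormal or size-dependent residual spread, between-stand
parameter heterogeneity, and real violations of component additivity
(sampling losses, unmeasured fractions). Passing tests therefore
demonstrate correctness of the inferential machinery under the model's
own assumptions, not robustness of the allometry to field data
pathologies.

## Validation experiments and problem sizes

`allobayes.experiments` (run by `scripts/acceptance.py` and asserted
in `tests/test_acceptance.py`) uses these sizes, chosen to give tight
Monte-Carlo error at desk scale:

- conjugate oracle: 39 trees, 50 000 fixed-σ² draws;
- flat-prior vs MLS: 39 trees, protocol-default chains, all five
  components;
- coverage: 100 replicates × 50 trees, 4 000-iteration chains
  (1 000 burn-in, unthinned) — ample for a near-iid sampler whose ESS
  is ~95% of chain length;
- elicitation recovery: 1 000 synthetic equations;
- small-n advantage: 100 replicates × 15 trees with a truth-centred
  32-equation prior, 3 000-iteration chains, evaluated **out of
  sample** on a fixed 500-tree stand. Out-of-sample predictive RMSE is
  the design choice here: in-sample RMSE structurally favours least
  squares (which minimises log-scale RSS on the fitting data), whereas
  the scientific claim being checked is about predicting new trees;
- additivity: 200 trees, MLS fits.

## Numerical choices and degenerate inputs

- Coefficient conditional sampled via Cholesky of the precision; a
  non-positive-definite precision raises rather than regularises.
- RSS is clamped at 0 against floating-point cancellation in the
  quadratic form.
- Noiseless data (σ² → 0) are handled: OLS reports σ̂² = 0 and the
  sampler's variance conditional concentrates near v·V/(v + n).
- A recorded total that disagrees with the component sum warns and is
  kept as measured, never silently fixed.
- Quantile intervals use numpy's default linear interpolation;
  constant chains yield zero-width intervals.

## Known limitations

- Single predictor ln(D²H) only; no D-only or two-predictor forms.
- No hierarchical/multi-site extension; one prior per component.
- Convergence tooling is ESS + Geweke on a single chain; no multi-chain
  R-hat.
- Literature equations are weighted equally in elicitation, ignoring
  the source studies' sample sizes.
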