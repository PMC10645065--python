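# Methods

## The model

The package rests on one distributional assumption: a behavioural trait
is normally distributed in the absence of constraint, and a constraint —
a ramp-like penalty that intensifies as the behaviour becomes more
extreme — skews the distribution so that the long tail points away from
the constrained side. The skew normal is the natural family for this:
its density is a normal density multiplied by a sigmoidal CDF factor,

    f(y) = (2/ω) φ((y − ξ)/ω) Φ(α (y − ξ)/ω),

and the sigmoidal factor, written with the error function as
`V_CDF(y) = 1 + erf(α(y − ξ)/(ω√2)) ∈ [0, 2]`, doubles as a model of the
constraint itself. Inverting and min–max normalizing it gives the
*constraint curve* `V_constraint = (max V_CDF − V_CDF)/(max V_CDF − min V_CDF)`,
a monotone map from trait values to a 0–1 "challenge" scale whose high
end is always the short-tail (constrained) side.

### Parameterizations

Two equivalent parameter triples are used. The **direct** form
(ξ, ω, α) is what the density above is written in. The **centered** form
(µ, σ, α) uses the population mean and SD; with
δ = α/√(1+α²) and m = δ√(2/π), the link is ω = σ/√(1 − m²),
ξ = µ − ωm. The centered form is the user-facing default because fitted
intercepts are then interpretable as means and SDs, and it is the
convention of the Bayesian regression software this model family is
usually fitted with. The population skewness of a skew normal is
γ₁ = ((4−π)/2) m³/(1−m²)^{3/2}, bounded by |γ₁| < ~0.99527; the inverse
map (used for starting values) is closed form via the cube root of
γ₁/((4−π)/2). Sampling uses the exact conditioning representation
(bivariate normal pair with correlation δ; reflect the second coordinate
on the sign of the first).

Infinite shape values are rejected everywhere; callers who want the
half-normal limit use a large finite α.

## Distributional regression

Each skew-normal parameter gets a linear predictor:
µᵢ = X_µ β_µ, log σᵢ = X_σ β_σ, αᵢ = X_α β_α + u_{g(i)}. The log link on
σ keeps the scale positive and makes the scale intercept interpretable on
the log scale. Random intercepts are supported on α only — in this
framework, between-individual differences in *constraint* are differences
in shape — with u_g ~ N(0, τ²).

Formulas use a deliberately small grammar: additive terms, treatment
coding with a declarable reference level (default: declared category
order, else first appearance), `(1|g)` and nested `(1|g1/g2)` random
intercepts. No interactions, transformations or random slopes.

### Estimation

Penalized maximum likelihood. Starting values are method-of-moments: OLS
for β_µ, log residual SD for the scale intercept, and residual skewness
per design cell inverted through the closed-form skewness map for β_α
(clipped inside the attainable range). The optimizer is L-BFGS-B with an
analytic gradient: the µ and log-σ derivatives are closed form and the α
derivative is one vectorized central difference, so a full gradient costs
a fixed handful of likelihood sweeps regardless of the number of
parameters. Three starts (the moment start, a sign-flipped-shape start —
skew-normal likelihoods are near-bimodal around α = 0 — and a jittered
start controlled by the seed) guard against local optima.

Random-effect variances are *not* jointly maximized with the deviations:
the joint objective is degenerate (u → 0, τ → 0 diverges). Instead τ is
updated EM-style: at fixed τ the inner problem solves for (β, u); then
τ² ← mean(u_g² + v_g), where v_g = 1/(I_g + 1/τ²) is the conditional
variance of u_g from the observed curvature I_g of the likelihood in u_g.
Iterated to a fixed point (tolerance 1e−3 on log τ, ≤ 25 iterations),
this accounts for shrinkage and converges to a positive variance whenever
the groups carry real signal.

### Intervals

Wald intervals from the observed information (numerical Hessian at the
optimum) for the mean and log-scale blocks. For the shape block, Wald
intervals are unreliable precisely where the scientific null lives: at
α = 0 the shape score is collinear with the location score and the
information matrix is singular, so Wald intervals under-cover near
symmetric data. Shape coefficients therefore get profile-likelihood
intervals (χ²₁ cutoff, bisection on the profile deviance; if the profile
stays flat out to a wide cap — possible in near-boundary fits — the cap
is returned). Empirically this restores ~95% coverage for the shape both
at α = 0 and at α = 3. Random-effect SDs are EM point updates and are
reported with degenerate intervals.

### Model comparison

`compare_models` estimates the difference in expected log predictive
density (elpd) by k-fold cross-validation (default k = 10): both model
specifications are refitted on each training fold and scored on the
held-out fold at population level (group deviations zeroed); the standard
error comes from the fold-wise differences. An `information_criterion`
method (log-likelihood minus parameter count, an AIC-style elpd estimate,
se = 0) is available as a fast approximation. Exact leave-one-out or
PSIS-LOO would only be meaningful for a sampling-based posterior and is
out of scope.

## Constraint curves and challenge scores

Curves are evaluated on a fixed grid: 512 points spanning the centered
mean ± 4 SD (the grid covers > 0.9999 of the mass, so the min–max
normalization effectively attains the full erf range). Taking the
extrema over the grid rather than over observed data makes curves
comparable across groups with different observed ranges. α = 0 is an
error, not a flat curve: the normalization divides by zero there, and
silently returning "no constraint everywhere" would be false precision.
Challenge scores interpolate the curve linearly; observations outside the
grid clamp to the endpoint values with a warning (the curve has plateaued
there).

## Trade-off preprocessing

For two-trait data with a forbidden region, the performance limit is the
τ = 0.05 quantile-regression line (pinball loss, via statsmodels
`QuantReg`). "Mixed" estimation — repeated measures per individual — is
implemented as fixed per-group intercept offsets rather than a full
random-effects quantile model: the estimand (a population limit line
with individual variation absorbed) is preserved at far lower complexity.
The returned line is the population line (mean of per-group intercepts);
offsets are reported separately. Deviation scores are the signed
orthogonal distances (y − a − bx)/√(1+b²): negative below the line, so
lower values mean higher performance when the limit is estimated from
below. The module is unit-agnostic; ratio-based bandwidth variables are
the caller's responsibility.

## The simulator

`generate_two_condition_dataset` encodes the study conditions used
throughout the tests: performance drawn from N(mean, 1) and penalized
one-sidedly above the target mean by b ↦ b/(1 + k(b − mean)); the
low-resource condition has mean 0 with k = 0.5, the high-resource
condition mean 1 with k = 0.1 (SD 1 in both; only the mean and penalty
strength differ between conditions). The penalty is applied only above
the mean because a two-sided application has a singularity at
b = mean − 1/k and produces unbounded artefacts; the one-sided ramp is
continuous, and monotone whenever k·mean < 1 (true of both study
conditions). Its output is capped near mean + 1/k, which gives the low
condition a near-hard ceiling at 2.

Default sample size for the two-condition analyses is 5000 per
condition, at which the fitted parameters sit tight around their
pseudo-true values (SDs across seeds are a few hundredths for the mean
and scale parameters).

What the generator emulates — and what it does not: it reproduces the
*statistical structure* of constrained performance (normal targets, ramp
penalties, a confound that masks pooled skew), not any real measurement
process. Real performance data add measurement noise, autocorrelation,
population mixing and selection effects, so passing tests on these
generators demonstrates the estimators' correctness and calibration
under the stated model, not robustness to every field condition. Note
also that penalty-generated data are *not* skew normal: fits to them
target pseudo-true values. In particular, the near-hard ceiling of the
low-resource condition drives the maximum-likelihood shape to rather
extreme values (α ≈ −9 at n = 5000/condition; an independent
implementation, scipy's `skewnorm.fit`, lands on the same optimum), so
shape estimates on such data should be read as "very strong constraint"
rather than as a calibrated physical quantity.

## Numerical choices

- Log densities use `log_ndtr` for the Gaussian CDF factor, so deep-tail
  evaluations never underflow.
- Non-finite objective values are replaced by a large finite penalty
  (1e10), keeping quasi-Newton line searches safe.
- Parameter-conversion round trips are accurate to 1e−10; curve
  normalization attains 0 and 1 to 1e−12.
- Bootstrap resampling is vectorized in chunks (bounded memory), with
  degenerate (zero-variance) resamples skipped, counted, and an error
  raised if they exceed 10%.
- Equivariance: shifting the response by a constant moves the mean
  intercept by that constant and leaves scale/shape estimates unchanged
  to ~1e−4 (optimizer tolerance).

## Known limitations

- Estimation is penalized ML, not full posterior inference; intervals
  are asymptotic (Wald/profile), and small-sample shape estimates are
  biased away from zero where a zero-centered prior would shrink them.
- Random intercepts are available on the shape only, and only as
  intercepts.
- The constraint curve is assumed sigmoidal; other constraint shapes are
  outside the family.
- One-dimensional traits only; the two-trait case is handled by the
  quantile-regression preprocessing, which does not propagate limit-line
  uncertainty into the downstream skew-normal fit.
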