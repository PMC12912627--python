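# Methods

## Model

The package centres on a four-parameter unit distribution obtained by
passing the Kumaraswamy cdf G(y) = 1 − (1 − y^κ)^γ through the
generalized Marshall–Olkin ratio transform

    F(y) = [λ z + (1 − λ) z²] / [α + (1 − α) z],     z = G(y),

with α, λ ∈ (0,1) and κ, γ > 0. The support convention is the open
interval: observed values equal to 0 or 1 are rejected at load time with
a row-level error rather than squeezed inward, because every statistic in
the package (log-densities, spacings, logit links) is undefined at the
boundary and silent squeezing would hide data problems.

Algebraic facts the implementation leans on:

- **Kumaraswamy collapse.** At α = λ the numerator factors against the
  denominator and F reduces to G exactly. This gives a cheap, exact
  oracle for tests and a natural starting point for optimization.
- **Survival factorization.** 1 − F = (1 − z)(α + (1 − λ) z) /
  (α + (1 − α) z), which keeps the hazard f/(1 − F) accurate as y → 1.
- **Analytic quantile.** F(y) = p reduces to the quadratic
  (1 − λ) z² + (λ − p(1 − α)) z − pα = 0 whose two real roots have
  opposite signs; the positive root, taken through the branch
  z = 2pα/(b + √D) when the linear coefficient b is positive, avoids
  cancellation and degrades gracefully into the linear limit as λ → 1.
  Sampling is inverse-transform from this quantile, so identical seeds
  give identical samples by construction.

All densities are computed on the log scale, with z evaluated through
expm1/log1p; this keeps fits stable for the large γ (order 100) that the
mortality and radar datasets demand.

Moments are computed by adaptive quadrature in quantile space,
E[Y^r] = ∫₀¹ Q(u)^r du, which sidesteps the density's endpoint
singularities for κ < 1 or γ < 1; the gamma-function series form is
provided (`series_moment`) as a resummed, geometrically convergent
series in (1 − α) and is cross-checked against quadrature in the tests.
The Lorenz curve is the normalized first incomplete moment
L(p) = (1/μ)∫₀^p Q(u) du and B(p) = L(p)/p.

The density's series expansion collapses its inner alternating binomial
sum to (1 − G)^k (1 − (k+2) G); the raw sum cancels catastrophically for
k beyond ~50, the collapsed form is exact and stable. Convergence is slow
near y = 0 (the tests therefore probe y ≥ 0.15 at truncation 4000).

## Estimation

Nine objectives (maximum likelihood, least squares, weighted least
squares, Anderson–Darling, Cramér–von Mises, maximum product spacing,
right-tail AD, minimum spacing absolute distance, minimum spacing
absolute-log distance) share one minimization convention and one
optimizer. Parameters are transformed to an unconstrained scale (logit
for α, λ and log for κ, γ and positive competitor parameters); starting
points are a baseline fit (the Kumaraswamy collapse for GMOKW, method of
moments for Beta) plus a seeded Latin hypercube over logit ∈ [−5.3, 5.3]
and log ∈ [log 0.05, log 500]; each start runs Nelder–Mead (fatol 1e−8)
and the best three candidates are polished by L-BFGS-B (ftol 1e−13).
Ties between starts break by lower objective, then lexicographically
smaller parameter vector. Defaults: 40 starts for the four-parameter
family, 10 for competitors, fixed seed 20240101. The likelihood is flat
and can be multimodal — in all three shipped datasets the optimum sits
on the near-boundary ridge α → 0 with inflated κ — which is why the
multi-start is generous.

Closed forms replace optimization where they exist: unit-Rayleigh
α̂ = n/Σ log² y_i, and the unit-Lindley score equation's positive
quadratic root.

Spacings D_i are first differences of the fitted cdf over order
statistics augmented with F = 0 and F = 1. Tied observations collapse a
spacing to zero; the affected log D_i is replaced by the log-density at
the tied point (the Cheng–Amin convention), keeping MPSE/MSALDE finite
on real data with repeated values. The two minimum-spacing objectives
are recentred by the uniform spacing 1/(n+1), making equal spacings
their exact minimizers.

Standard errors (MLE only) are square roots of the diagonal of the
inverse numerically differentiated Hessian of the negative
log-likelihood at the optimum.

## Goodness of fit and model selection

EDF statistics use F_i = F(y_(i)): KS = max_i max(i/n − F_i,
F_i − (i−1)/n), the (2i−1)-weighted Anderson–Darling sum, and
CvM = 1/(12n) + Σ (F_i − (2i−1)/(2n))². The AD statistic and the ADE
estimation objective are the same formula evaluated at different
parameters, and a test asserts their equality.

Approximate p-values use the classical all-parameters-known asymptotics:
the Kolmogorov series on √n·KS, the Marsaglia–Marsaglia (2004)
polynomial/exponential approximation to the AD limit law, and the
Anderson–Darling (1952) Bessel-K series for the CvM limit. Parameters
here are estimated, so these p-values are conventional summaries, not
exact test levels; they are monotone in their statistics and accurate at
the classical reference points (checked in tests).

Information criteria from ℓ̂, k parameters, n observations:
AIC = −2ℓ̂ + 2k, BIC = −2ℓ̂ + k log n, CAIC = AIC + 2k(k+1)/(n−k−1),
HQIC = −2ℓ̂ + 2k log log n. `compare_models` ranks families by AIC and
keeps non-converging families in the table as explicit failures.

## Monte Carlo harness

Three built-in truth scenarios — (0.25, 0.5, 1.2, 1.5),
(0.2, 0.7, 0.5, 0.75), (0.25, 0.75, 2, 3) — with sample sizes
{50, 100, 250, 500, 750, 1000} and N = 1000 replicates (N = 250 in the
reduced mode used for the large-n summaries). Per-replicate seeds derive
from SeedSequence(case seed, n, replicate), so any cell is reproducible
in isolation and cells are independently parallelizable. Bias and MSE
are plain averages of (estimate − truth) and its square; replicates
where a method fails are excluded from that method's averages and
counted, because silently averaging boundary junk corrupts the MSE.

**Protocol choice (consistent-root tracking).** Because the likelihood
surface is ridged, the global maximizer at small-to-moderate n often
lies on the α → 0 ridge far from the truth, and its bias/MSE summaries
are dominated by optimizer geometry rather than sampling error (at
n = 1000 under scenario 1, global multi-start gives MSE(λ̂) ≈ 0.10
against ≈ 0.01 for the local root). The harness therefore starts each
replicate's optimization at the true parameters and converges locally —
the consistent root is the object classical MLE asymptotics describe
when multiple roots exist, and tracking it is the conventional protocol
of estimator-comparison simulation studies. Global multi-start per
replicate remains available (`start_at_truth=False`, larger `n_starts`)
for studying the global maximizer itself.

Problem sizes in the shipped tests and acceptance script — N = 1000 at
n = 50 and N = 250 at n = 1000 for the headline cells, reduced N for
trend checks — were chosen so a full run completes in about a minute on
one CPU while keeping Monte Carlo standard errors on the reported cells
below ~0.01.

## Quantile regression

Fixing a level p (default 0.5, median regression; any p ∈ (0,1) is
accepted), the first Kumaraswamy shape is re-expressed through the
quantile inversion: κ\*(μ) = log(1 − (1 − z_p)^{1/γ}) / log μ, where z_p
is the Marshall–Olkin quadratic root at p. By construction μ is then the
p-th quantile of the distribution, to within 1e−10 over randomized
parameter draws (a definitional test). The regression links
μ_i = expit(x_i'β); the log-likelihood is the exact sum of the
reparameterized log-densities — a pure substitution, no separate density
code path.

Fitting maximizes over (logit α, logit λ, log γ, β) with the same
multi-start machinery (starting β from an OLS fit of logit(t) on X).
The observed information is differentiated numerically on the
unconstrained scale — much better conditioned when a tilt parameter
saturates — and mapped back by the delta method. A saturated tilt
(λ̂ → 1 happens on simulated data) leaves a genuine null direction in
the information matrix: those components report SE = NaN with a warning
while the identified block, in particular β, keeps valid Wald
inference (z = β̂/SE against the standard normal).

## Synthetic data

`generate_sample` draws from any family with an analytic quantile by
inverse transform. `generate_regression_data` draws independent standard
normal covariates by default, forms μ_i through the logit link, and
samples each response from the reparameterized distribution at μ_i. The
generators emulate exactly the model the estimators assume: i.i.d.
observations, correctly specified family, covariates independent of the
noise. Passing recovery/coverage tests therefore demonstrates internal
correctness of the likelihood, optimizer and information matrix — not
robustness to misspecification, dependence, measurement error or
covariate outliers, none of which the generators produce.

## Limitations

- The tilt pair (α, λ) is weakly identified at realistic sample sizes:
  profile likelihoods are flat along a ridge, estimates can sit at
  α ≈ 0, and their SEs should be read with care. κ and γ are well
  identified.
- Reported EDF p-values ignore parameter estimation (see above).
- The regression information matrix can be singular along a saturated
  tilt direction; the package reports NaN SEs for the affected
  components rather than suppressing the fit.
- The radar fixture keeps all 101 printed observations at full
  precision; analyses that drop the final observation will differ
  slightly in every statistic.
- Quantile round-trips are exact to 1e−9 where the density is
  appreciable; in regions with density below ~1e−7 the composition
  Q(F(y)) is limited by double precision itself (ε/f(y)), a conditioning
  bound no implementation can beat.
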