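# gmokw

Fitting and inference for the **generalized Marshall–Olkin Kumaraswamy
(GMOKW)** distribution — a four-parameter family on the open unit interval
for proportions, rates, shares and normalized intensities — together with
nine classical estimators, goodness-of-fit model selection against six
competitor unit distributions, a Monte Carlo bias/MSE harness, and a
logit-link quantile-regression model for bounded responses.

It is aimed at statisticians and applied researchers (epidemiology,
political science, remote sensing, education) who model data confined to
(0,1) and want a more flexible alternative to the Beta and Kumaraswamy
laws, including bathtub and increasing–decreasing–increasing hazard
shapes.

## The model

Pass the Kumaraswamy baseline G(y) = 1 − (1 − y^κ)^γ through the
two-parameter generalized Marshall–Olkin ratio transform. With
z = 1 − (1 − y^κ)^γ,

```
F(y; α, λ, κ, γ) = [λ z + (1 − λ) z²] / [α + (1 − α) z],
f(y; α, λ, κ, γ) = [(1−α)(1−λ) z² + 2α(1−λ) z + αλ] / [α + (1−α) z]²
                   × κ γ y^{κ−1} (1 − y^κ)^{γ−1},
```

with tilt parameters α, λ ∈ (0,1) and shapes κ, γ > 0. When α = λ the
tilt cancels and the family collapses exactly to Kumaraswamy(κ, γ). The
quantile function is analytic: solve the quadratic
(1−λ) z² + (λ − p(1−α)) z − pα = 0 for the root z ∈ [0,1] and invert the
Kumaraswamy transform — which also gives exact inverse-transform
sampling and the quantile reparameterization used for regression.

**Estimation.** Maximum likelihood plus eight minimum-distance /
spacings objectives (LSE, weighted LSE, Anderson–Darling, Cramér–von
Mises, maximum product spacing, right-tail AD, minimum spacing absolute
and absolute-log distance), all minimized over logit/log-transformed
parameters with a seeded multi-start (Latin hypercube + a
Kumaraswamy-collapse start), Nelder–Mead refined by L-BFGS-B.

**Quantile regression.** Fixing a level p, the shape κ is re-expressed
as κ\*(μ) so that μ is the p-th quantile; μ_i = expit(x_i'β) links the
conditional quantile to covariates, and Wald inference comes from the
observed information matrix (numerically differentiated on the
unconstrained scale, delta-method back).

## Worked example

Three application datasets ship with the package: 49 US Electoral College
vote shares, 60 UK daily mortality rates, and 101 EMISAR radar
backscatter intensities.

```python
from gmokw import UnitDistributionFitter, load_fixture

d = load_fixture("dataset_I")           # electoral vote shares, n=49
est = UnitDistributionFitter(family="gmokw", method="mle").fit(d.sample.values)
print(est.params_.round(4))             # [0.0223 0.6901 9.3931 1.9843]
print(est.se_.round(4))                 # [0.0233 0.1196 1.9924 0.7798]
print(round(est.neg2loglik_, 4))        # -54.5747
```

The fitted tilt α̂ ≈ 0.022 sits near its boundary — the likelihood uses
the Marshall–Olkin tilt aggressively — with shapes κ̂ ≈ 9.39, γ̂ ≈ 1.98;
−2 log ℓ = −54.57 is the model's headline fit quality on these data.
Model comparison from the command line:

```
$ gmokw compare --fixture dataset_I --families gmokw,kw,ur,beta
        -2logL      AIC      BIC     CAIC     HQIC     KS     AD    CvM  p(KS)  p(AD)  p(CvM)
gmokw -54.5747 -46.5747 -39.0074 -45.6656 -43.7037 0.0669 0.4076 0.0485 0.9807 0.8412  0.8854
ur    -47.1707 -45.1707 -43.2788 -45.0856 -44.4529 0.1084 1.2593 0.1502 0.6125 0.2460  0.3890
beta  -45.6753 -41.6753 -37.8917 -41.4145 -40.2398 0.1355 1.1865 0.1953 0.3292 0.2728  0.2767
kw    -44.5502 -40.5502 -36.7666 -40.2893 -39.1147 0.1340 1.2653 0.2097 0.3424 0.2440  0.2495
```

GMOKW attains the lowest −2 log ℓ, AIC, CAIC and all three EDF statistics
(KS/AD/CvM): the four-parameter family buys a materially better fit than
the two-parameter competitors. The CLI also exposes `fit`, `simulate`
(the bias/MSE harness) and `regress` (quantile regression on a CSV).

Regression, sklearn-style:

```python
from gmokw import GMOKWQuantileRegressor, generate_regression_data

d = generate_regression_data([0.5, -1.0], alpha=0.4, lam=0.6, gamma=2.0,
                             p=0.5, n=500, seed=42)
reg = GMOKWQuantileRegressor(p=0.5).fit(d.design[:, 1:], d.response.values)
print(reg.intercept_.round(3), reg.coef_.round(3))   # 0.486 [-1.021]
```

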