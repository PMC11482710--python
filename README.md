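# lomaxlink

Bayesian binary regression with **asymmetric double-Lomax link functions**
for imbalanced classification problems.

## The problem

In binary regression the link function F maps the linear predictor
η = x'β to a success probability p = F(η). The usual links (logit, probit)
are symmetric: they approach 0 and 1 at the same rate, which implicitly
assumes the two classes behave symmetrically. When one class heavily
outnumbers the other — diseased vs healthy trees, donors vs non-donors,
defaults vs non-defaults — a *skewed* link that rises toward one class
faster than the other can fit markedly better and separate the classes more
cleanly in its predictive probabilities.

This package implements a link family built from the **double Lomax
(DLomax) distribution** — the heavy-tailed law of the ratio of two i.i.d.
standard Laplace variables, with cdf

    G(x) = 1/(2(1 − x))          for x ≤ 0,
    G(x) = 1 − 1/(2(1 + x))      for x > 0,

made asymmetric by a single exponent λ > 0:

- **PDLomax** (power):          F_P(x | λ) = G(x)^λ
- **RPDLomax** (reverse power): F_RP(x | λ) = 1 − G(−x)^λ

λ = 1 recovers the symmetric base in both cases; λ < 1 and λ > 1 skew the
curve in opposite directions, so one extra interpretable parameter spans a
family of class-imbalance shapes.

## The model

For observations (yᵢ, xᵢ), i = 1…n:

    yᵢ | β, λ ~ Bernoulli(pᵢ),    pᵢ = F_λ(xᵢ'β)

with priors βⱼ ~ N(0, 10²) and δ = log λ ~ Uniform(−2, 2), so λ is
restricted a priori to (e⁻², e²) ≈ (0.14, 7.39). The posterior is sampled
with an in-package No-U-Turn Sampler (analytic gradients for every link,
dual-averaged step size, diagonal mass adaptation), and convergence is
monitored with split R-hat. Fits are compared with DIC, EAIC, EBIC, WAIC
and importance-sampling leave-one-out cross-validation (truncated weights
wᵢ⁽ˢ⁾ = min(rᵢ⁽ˢ⁾, √S·r̄ᵢ), with generalized-Pareto smoothing available),
and checked with randomized quantile residuals, which are standard normal
under a correctly specified model.

The classical links logit, probit, cauchit, loglog and cloglog are included
for comparison, plus a *power Cauchy* response used as a deliberately
misspecified generator in the simulation experiments.

## Worked example

Simulate from an RPDLomax(λ=2) model and refit it:

```python
import lomaxlink as ll

data = ll.simulate_binary(ll.LinkSpec("rpdlomax", 2.0), beta=(0.0, 1.0),
                          n=2000, seed=42)
res = ll.BernoulliLinkModel(data, "rpdlomax").fit(
    chains=4, iterations=600, warmup=300, seed=7)
print(res.summary().round(3))
```

```
            mean     sd  median     p5    p95   rhat
parameter
beta0      0.042  0.108   0.038 -0.123  0.221  1.005
beta1      0.996  0.079   0.994  0.876  1.125  1.005
lambda     2.016  0.130   2.011  1.806  2.244  1.005
```

The posterior means recover the generating values β = (0, 1), λ = 2; the λ
row summarises exp(δ) draws directly (mean, SD, median, 5%/95%
percentiles), and R-hat ≈ 1 confirms the four chains mixed. Model-choice
metrics and class-conditional predictive summaries follow from the same
results object:

```python
res.deviance_summary().DIC   # 1679.79
res.waic().WAIC              # 1679.77
res.loo().LOO                # 1679.80   (deviance scale, -2·elpd)
print(res.class_predictive_summary().round(3))
```

```
          min     q1  median   mean     q3    max
success  0.24  0.638   0.935  0.797  0.973  0.984
failure  0.24  0.283   0.350  0.423  0.493  0.984
```

Observed successes receive a much higher median predictive probability
(0.935) than observed failures (0.350) — the class separation the
asymmetric link is designed to deliver.

A command-line interface covers the same workflow end to end
(`lomaxlink fit | compare | simulate | recover | misspec | predict`), e.g.

```sh
lomaxlink compare mydata.csv --response y --links logit,dlomax,rpdlomax \
    --iterations 5000 --warmup 2500 --seed 1 --outdir out/
```

writes per-link draw CSVs, residual plots and a comparison table with
ρ_d, D̄, D̂, DIC, EAIC, EBIC, LOO and WAIC columns.

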