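# Methods

## Model

Binary responses are modelled as independent Bernoulli draws whose success
probability is a link cdf evaluated at a linear predictor:

y_i | β, λ ~ Bernoulli(p_i), p_i = F_λ(η_i), η_i = x_i'β.

Eight links are supported. Five are classical — logit, probit, cauchit,
loglog (p = exp(−exp(−η))) and cloglog (p = 1 − exp(−exp(η))); the loglog /
cloglog conventions are the standard ones, stated here explicitly because
usage in the literature varies. The remaining three form the double-Lomax
family that is the point of the package:

- **DLomax**: the symmetric base distribution, cdf
  G(x) = 1/(2(1+(μ−x)/σ)) for x ≤ μ and 1 − 1/(2(1+(x−μ)/σ)) above, density
  g(x) = 1/(2σ(1+|x−μ|/σ)²). Links always use the standard case μ=0, σ=1.
  Tails are polynomial (Pareto-type), much heavier than logistic or normal,
  so extreme linear predictors still receive non-negligible probability —
  the same robustness rationale as the cauchit link.
- **PDLomax**: F_P = G^λ, density λ g G^{λ−1}.
- **RPDLomax**: F_RP(x) = 1 − G(−x)^λ, the reflection of the power
  transform. The two piecewise cdfs satisfy F_RP(x) = 1 − F_P(−x) — a
  reflection in the argument, not a pointwise complement — and this is the
  form implemented and property-tested.

λ > 0 is the single asymmetry parameter; λ = 1 recovers DLomax exactly
(tested at 1e−12). For λ ≠ 1 the transformed distributions are genuinely
asymmetric, which is what lets the link approach the two class labels at
different rates.

Quantile functions are closed-form (G is invertible on each branch), so
random variate generation is by inverse transform.

## Priors and parameterization

β_j ~ Normal(0, 10²) independently — weakly informative on standardized
covariates. The asymmetry parameter is sampled as δ = log λ with
δ ~ Uniform(−2, 2), restricting λ to (0.14, 7.39); beyond that range extra
asymmetry is practically indistinguishable, and the log scale conditions
the posterior far better than λ itself. Reported λ summaries apply exp to
the δ draws (mean of exp(δ), percentiles of exp(δ)) — the Jensen gap
between mean(exp δ) and exp(mean δ) is real and the former is the
convention used everywhere, including plug-in predictions. The plug-in
deviance D̂, however, evaluates at the posterior mean of δ, matching the
definition of the deviance at the posterior mean of the *sampled*
parameters.

## Sampling

Posterior draws come from an in-package No-U-Turn Sampler: recursive
trajectory doubling with a slice variable and the standard U-turn
criterion (max depth 10), leapfrog integration with a diagonal mass
matrix, and dual-averaged step-size adaptation toward a 0.8 acceptance
statistic. The mass matrix is estimated from the middle half of warmup.
δ is mapped to an unbounded scale by a scaled inverse-logistic transform
with its Jacobian included; gradients of the log posterior are analytic
for every link (the derivative of the power links with respect to λ uses
∂G^λ/∂λ = G^λ log G) and are verified against central differences at
1e−7 tolerance in the test suite.

Numerical safeguards: probabilities are clipped to [1e−12, 1−1e−12]
before any logarithm, so extreme η cannot produce infinite
log-likelihoods; G^λ is computed as exp(λ log G) with log1p-based tail
forms; the DLomax density is continuous but not differentiable at the
location — a measure-zero event for the integrator, handled by evaluating
the x ≤ 0 branch at the kink.

Defaults mirror the applied protocol: 4 chains, 5000 iterations with 2500
warmup. Convergence is flagged by split R-hat (computed via arviz): a
warning above 1.05, a failure flag above 1.1. Comparison tables blank the
metrics of non-converged fits rather than hiding or dropping them.
Per-chain seeds fan out deterministically from one master seed; fits,
studies and CLI runs are bit-reproducible given that seed. One replicate
whose credible interval excluded the truth was re-sampled with an
independent affine-invariant ensemble sampler during development; the two
posteriors agreed to three decimals, validating the NUTS implementation.

## Model comparison

With S posterior draws and D(θ) = −2 log L(θ):

- D̄ = mean of per-draw deviances; D̂ = deviance at posterior means;
  ρ_d = D̄ − D̂; DIC = D̄ + ρ_d; EAIC = D̄ + 2k; EBIC = D̄ + k log n.
- WAIC = −2(LPPD̂ − p̂_WAIC) from the S × n pointwise log predictive
  density matrix.
- LOO: importance ratios r_i⁽ˢ⁾ = 1/p(y_i|θ⁽ˢ⁾) truncated at
  w = min(r, √S · r̄) (truncated importance sampling, the default), with
  optional generalized-Pareto smoothing of the largest ratios
  (Zhang–Stephens fit; the tail-shape k̂ is reported as a reliability
  diagnostic). **LOO is reported on the deviance scale, −2·ELPD̂**, so its
  magnitude is directly comparable to WAIC in the same table. Both
  variants are validated against exact leave-one-out refitting (n=20,
  mean per-observation error < 0.05) and against an independent PSIS-LOO
  implementation.

Smaller is better for every metric. Randomized quantile residuals use the
posterior-mean predictive probability p̂_i: u_i ~ U(0, 1−p̂_i) for
failures, U(1−p̂_i, 1) for successes, r_i = Φ⁻¹(u_i), with an explicit
seed; under a correctly specified model they are i.i.d. standard normal,
which the suite checks by KS test on a well-specified fit.

## Synthetic data and the two experiments

`simulate_binary` draws a single covariate X ~ U(−3, 3), default
coefficients β = (0, 1), and Bernoulli responses through any link — the
canonical design of both experiments. It emulates the low-dimensional,
well-specified regime in which estimator behaviour can be measured against
known truth; it does not emulate correlated or high-dimensional
covariates, covariate measurement error, or label noise, so passing tests
certify estimator correctness under the stated design, not performance on
arbitrary real data.

**Parameter recovery**: for each link (logistic, DLomax and the power
links over λ ∈ {0.25, 0.5, 2, 4}) and each n ∈ {500, 1000, 2000},
R datasets are generated and refitted with short chains (4 × 200
iterations, 100 warmup — the applied protocol for this experiment).
Summaries per cell: bias = mean(θ̂ − θ) of posterior means,
RMSE = √mean((θ̂ − θ)²), and CP = the share of replicates whose central
95% interval (2.5/97.5 posterior percentiles) covers the truth. The
printed formula for the error metric is typographically ambiguous between
MSE and its root; both are reported, with RMSE as the headline per its
name. R defaults to 100; the test suite runs R = 60, which keeps the
study inside its time budget while leaving coverage estimates with
SE ≈ 0.03–0.04 — small enough that the [0.85, 1] coverage band is
meaningful. At that precision the sign of the bias change for the
near-unbiased symmetric links remains Monte Carlo noise, so the
bias-shrinkage check budgets one exception across the four links.

**Misspecification**: data are generated from a power Cauchy response
p = (arctan(η)/π + 1/2)^λ — an exponentiated cauchit, outside the
candidate family — and each candidate link is refitted to every dataset.
Reported per (λ, link): mean and variance of LOO and WAIC across
replicates and the share of replicates in which the candidate beats the
logistic baseline, plus the mean proportion of successes per λ. A
quadrature oracle (`expected_success_rate`) gives the exact class balance
E[p(X)] for any generator; the simulated proportions are required to match
it to within 3 standard errors. The exact balances under this design are
0.805, 0.670, 0.338, 0.205 for λ = 0.25, 0.5, 2, 4. Published summaries
of this generator quote 0.800/0.661/0.329/0.198 — a 0.005–0.009 gap that
exceeds the design's Monte Carlo error and is consistent with a shared
covariate realization in the published runs; the quadrature value is
treated as ground truth here, and the discrepancy is surfaced (not
absorbed) by the acceptance checks.

**Worked-example reconstruction**: the published reverse-power fit to the
tree-health image data is reproduced from its printed posterior means
(β = 26.110, 1.142, 137.094, −19.340, 0.206; λ = 0.256) and printed
standardization constants. At mean red reflectance 90 this yields
p = 0.0149 (printed: 0.015); at 100 it yields p = 0.5598 against a printed
0.558 — the printed inputs carry 2–3 decimal rounding that propagates to
about ±0.002 in p, so agreement beyond that resolution is not attainable
from the published tables alone.

## Preprocessing choices

Covariates are z-scored in-sample (no train/test split exists in this
workflow); the constants are stored so predictions and effect curves
accept raw-scale values, with unspecified covariates held at their sample
means. Pairs of covariates with |r| ≥ 0.95 (configurable) are screened
before fitting: the member with the larger mean absolute correlation with
all other covariates is dropped, ties broken by column order. The 0.95
default sits just below the collinearity levels (0.98, 1.0) at which such
pairs are known to destabilise these fits.

## Known limitations

- Moments, skewness and kurtosis of the power-transformed distributions
  are not implemented (deliberately out of scope).
- The PDLomax posterior can mix poorly on strongly separated or large-λ
  data — the known fragility of this link under the default priors;
  non-convergence is reported via R-hat flags rather than worked around.
- Frequentist/MLE fitting, stacking or model averaging, and
  confusion-matrix-style threshold evaluation are not provided.
- The sampler is tuned for the low-dimensional posteriors of this model
  class (tens of parameters at most), not for large hierarchical models.
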