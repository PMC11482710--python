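"""Bayesian Bernoulli regression with interchangeable link functions.

The model, for observations (y_i, x_i), i = 1..n:

    y_i | β, λ ~ Bernoulli(p_i),      p_i = F_λ(η_i),      η_i = x_i'β,

where F_λ is the cdf of the chosen link distribution.  Priors are weakly
informative and match common practice for standardized covariates:

    β_j ~ Normal(0, 10²)  independently,
    δ = log λ ~ Uniform(−2, 2)   (power links only),

so the asymmetry parameter λ is restricted a priori to (e⁻², e²) ≈
(0.14, 7.39); outside that range additional asymmetry is practically
indistinguishable.  δ rather than λ is sampled because the log scale makes
the posterior geometry far better conditioned.

Estimation is by NUTS (``lomaxlink.sampler``) on (β, z) where z is an
unbounded reparameterization of δ (scaled inverse-logistic, Jacobian
included).  The posterior mean is the point-estimate convention throughout,
and λ summaries are computed by applying exp to the δ draws — mean(exp δ),
not exp(mean δ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import links as lk
from .data import BinaryDataset
from .sampler import nuts_sample

__all__ = [
    "PriorSpec",
    "FitConfig",
    "PosteriorDraws",
    "BernoulliLinkModel",
    "BernoulliLinkResults",
    "ConvergenceWarning",
    "log_likelihood",
    "log_posterior",
    "pointwise_loglik",
    "predictive_prob_matrix",
]

RHAT_WARN = 1.05
RHAT_FAIL = 1.10


class ConvergenceWarning(UserWarning):
    """Emitted when MCMC diagnostics indicate unreliable draws."""


@dataclass(frozen=True)
class PriorSpec:
    """Priors: β_j ~ N(0, beta_sd²); δ = log λ ~ U(delta_low, delta_high)."""

    beta_sd: float = 10.0
    delta_low: float = -2.0
    delta_high: float = 2.0

    def __post_init__(self) -> None:
        if not self.beta_sd > 0:
            raise ValueError("beta_sd must be positive")
        if not self.delta_low < self.delta_high:
            raise ValueError("delta_low must be below delta_high")

    @property
    def lam_support(self) -> tuple[float, float]:
        """Implied support of λ = exp(δ)."""
        return (float(np.exp(self.delta_low)), float(np.exp(self.delta_high)))


@dataclass(frozen=True)
class FitConfig:
    """Sampler run lengths; ``iterations`` counts warmup, per chain."""

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    seed: "int | np.random.SeedSequence | None" = 0
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are needed for R-hat")


@dataclass
class PosteriorDraws:
    """Joint posterior draws; ``delta`` is None for λ-free links."""

    beta: np.ndarray           # S x k
    delta: np.ndarray | None   # S or None
    chain_id: np.ndarray       # S

    @property
    def S(self) -> int:
        return self.beta.shape[0]

    @property
    def lam(self) -> np.ndarray | None:
        return None if self.delta is None else np.exp(self.delta)


# ---------------------------------------------------------------------------
# likelihood / posterior densities (module-level, array in / scalar out)
# ---------------------------------------------------------------------------

def _probs(eta, link: lk.LinkSpec, lam: float | None):
    return lk.link_prob(eta, link, lam=lam)


def log_likelihood(
    beta: np.ndarray,
    delta: float | None,
    data: BinaryDataset,
    link: lk.LinkSpec | str,
) -> float:
    """Bernoulli log likelihood Σ yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)."""
    link = lk.LinkSpec(link) if isinstance(link, str) else link
    beta = np.asarray(beta, dtype=float)
    if beta.size != data.k:
        raise ValueError(f"beta has length {beta.size}, expected {data.k}")
    if data.n == 0:
        return 0.0
    lam = float(np.exp(delta)) if (link.has_shape and delta is not None) else None
    eta = data.X @ beta
    p = np.asarray(_probs(eta, link, lam))
    return float(np.sum(data.y * np.log(p) + (1.0 - data.y) * np.log1p(-p)))


def log_posterior(
    beta: np.ndarray,
    delta: float | None,
    data: BinaryDataset,
    link: lk.LinkSpec | str,
    priors: PriorSpec | None = None,
) -> float:
    """Unnormalized log posterior: likelihood + N(0,σ²) β prior + flat δ."""
    priors = priors or PriorSpec()
    link = lk.LinkSpec(link) if isinstance(link, str) else link
    beta = np.asarray(beta, dtype=float)
    if link.has_shape:
        if delta is None:
            raise ValueError("power links require a delta value")
        if not (priors.delta_low < delta < priors.delta_high):
            return -np.inf
    lp = log_likelihood(beta, delta, data, link)
    lp += float(-0.5 * np.sum(beta**2) / priors.beta_sd**2)
    return lp


def predictive_prob_matrix(
    beta_draws: np.ndarray,
    lam_draws: np.ndarray | None,
    X: np.ndarray,
    link: lk.LinkSpec | str,
) -> np.ndarray:
    """Success probabilities for every draw and row of ``X`` (S × n)."""
    link = lk.LinkSpec(link) if isinstance(link, str) else link
    eta = np.atleast_2d(beta_draws) @ np.atleast_2d(X).T
    if link.name == "pdlomax":
        p = np.exp(lam_draws[:, None] * lk._log_G(eta))
    elif link.name == "rpdlomax":
        p = -np.expm1(lam_draws[:, None] * lk._log_G(-eta))
    elif link.name == "dlomax":
        p = lk.dlomax_cdf(eta)
    else:
        p = lk._classical_cdf(link.name, eta)
    return np.clip(p, lk.PROB_CLIP, 1.0 - lk.PROB_CLIP)


def pointwise_loglik(
    beta_draws: np.ndarray,
    delta_draws: np.ndarray | None,
    data: BinaryDataset,
    link: lk.LinkSpec | str,
) -> np.ndarray:
    """S × n matrix of log p(y_i | θ⁽ˢ⁾), the basis of WAIC and LOO."""
    lam = None if delta_draws is None else np.exp(np.asarray(delta_draws))
    p = predictive_prob_matrix(beta_draws, lam, data.X, link)
    y = data.y[None, :]
    return y * np.log(p) + (1.0 - y) * np.log1p(-p)


# ---------------------------------------------------------------------------
# gradient of the log posterior on the sampling scale
# ---------------------------------------------------------------------------

def _make_logpost_and_grad(data: BinaryDataset, link: lk.LinkSpec, priors: PriorSpec):
    """Return f(theta) -> (logp, grad) on the unconstrained scale.

    theta = (β, z) with δ = lo + (hi−lo)·sigmoid(z) for power links, else
    theta = β alone.  The inverse-logistic Jacobian is included.
    """
    X, y = data.X, data.y
    k = X.shape[1]
    lo, hi = priors.delta_low, priors.delta_high
    width = hi - lo
    sd2 = priors.beta_sd**2
    has_shape = link.has_shape

    def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta = theta[:k]
        grad = np.empty_like(theta)
        if has_shape:
            z = theta[k]
            s = 1.0 / (1.0 + np.exp(-z))
            delta = lo + width * s
            lam = np.exp(delta)
        else:
            lam = None

        logp = -0.5 * np.sum(beta**2) / sd2
        grad[:k] = -beta / sd2
        if has_shape:
            # log-Jacobian of the sigmoid transform (computed on the log
            # scale so saturation of s never produces log(0)) and its grad
            logp += np.log(width) - np.logaddexp(0.0, -z) - np.logaddexp(0.0, z)
            grad[k] = 1.0 - 2.0 * s

        if data.n:
            eta = X @ beta
            p = np.asarray(lk.link_prob(eta, link, lam=lam))
            logp += float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
            w = (y - p) / (p * (1.0 - p))
            f_eta = np.asarray(lk.link_pdf(eta, link, lam=lam))
            grad[:k] += X.T @ (w * f_eta)
            if has_shape:
                dp_dlam = np.asarray(lk.link_dprob_dlam(eta, link, lam))
                dldlam = float(np.sum(w * dp_dlam))
                grad[k] += dldlam * lam * width * s * (1.0 - s)
        return float(logp), grad

    return f


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class BernoulliLinkModel:
    """Bernoulli regression model with a chosen link, built from data.

    Parameters
    ----------
    data : BinaryDataset
        Response and design matrix (intercept column first).
    link : LinkSpec or str
        One of 'logit', 'probit', 'cauchit', 'loglog', 'cloglog', 'dlomax',
        'pdlomax', 'rpdlomax'.  For the two power links the asymmetry
        parameter λ is estimated from the data.
    priors : PriorSpec, optional
    """

    def __init__(
        self,
        data: BinaryDataset,
        link: lk.LinkSpec | str,
        priors: PriorSpec | None = None,
    ) -> None:
        self.data = data
        self.link = lk.LinkSpec(link) if isinstance(link, str) else link
        self.priors = priors or PriorSpec()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        link: lk.LinkSpec | str,
        standardize: bool = True,
        correlation_threshold: float | None = None,
        priors: PriorSpec | None = None,
    ) -> "BernoulliLinkModel":
        """Build a model from a pandas DataFrame (see ``data.load_csv``)."""
        import io

        from .data import load_csv

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        dataset, _ = load_csv(
            buf, response, standardize=standardize,
            correlation_threshold=correlation_threshold,
        )
        return cls(dataset, link, priors=priors)

    # -- densities ----------------------------------------------------------

    def log_likelihood(self, beta, delta: float | None = None) -> float:
        return log_likelihood(beta, delta, self.data, self.link)

    def log_posterior(self, beta, delta: float | None = None) -> float:
        return log_posterior(beta, delta, self.data, self.link, self.priors)

    # -- estimation ---------------------------------------------------------

    def fit(self, config: FitConfig | None = None, **kwargs) -> "BernoulliLinkResults":
        """Sample the posterior with NUTS; returns a results object.

        Keyword arguments override fields of ``config`` (chains, iterations,
        warmup, seed, target_accept).
        """
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace

            config = replace(config, **kwargs)
        k = self.data.k
        dim = k + self.link.n_shape
        logpost = _make_logpost_and_grad(self.data, self.link, self.priors)

        seed = config.seed
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        chain_seeds = ss.spawn(config.chains)
        n_keep = config.iterations - config.warmup
        all_draws = np.empty((config.chains, n_keep, dim))
        diags = []
        for c in range(config.chains):
            rng = np.random.default_rng(chain_seeds[c])
            x0 = np.zeros(dim)
            x0[:k] = 0.1 * rng.standard_normal(k)
            if self.link.has_shape:
                x0[k] = 0.5 * rng.standard_normal()
            draws, diag = nuts_sample(
                logpost,
                x0,
                n_iter=config.iterations,
                warmup=config.warmup,
                rng=rng,
                target_accept=config.target_accept,
            )
            all_draws[c] = draws
            diags.append(diag)

        beta = all_draws[:, :, :k].reshape(-1, k)
        chain_id = np.repeat(np.arange(config.chains), n_keep)
        if self.link.has_shape:
            z = all_draws[:, :, k].reshape(-1)
            s = 1.0 / (1.0 + np.exp(-z))
            delta = self.priors.delta_low + (
                self.priors.delta_high - self.priors.delta_low
            ) * s
        else:
            delta = None

        res = BernoulliLinkResults(
            model=self,
            draws=PosteriorDraws(beta=beta, delta=delta, chain_id=chain_id),
            config=config,
            chain_shape=(config.chains, n_keep),
            sampler_diagnostics=diags,
        )
        max_rhat = np.nanmax(list(res.rhat.values()))
        if max_rhat > RHAT_FAIL:
            warnings.warn(
                f"convergence failure: max R-hat = {max_rhat:.3f} > {RHAT_FAIL}",
                ConvergenceWarning,
                stacklevel=2,
            )
        elif max_rhat > RHAT_WARN:
            warnings.warn(
                f"possible non-convergence: max R-hat = {max_rhat:.3f} > {RHAT_WARN}",
                ConvergenceWarning,
                stacklevel=2,
            )
        return res


class BernoulliLinkResults:
    """Posterior draws plus summaries, diagnostics and predictions."""

    def __init__(self, model, draws, config, chain_shape, sampler_diagnostics):
        self.model = model
        self.draws = draws
        self.config = config
        self.chain_shape = chain_shape
        self.sampler_diagnostics = sampler_diagnostics
        self._rhat: dict[str, float] | None = None
        self._loglik: np.ndarray | None = None

    # -- basic accessors ----------------------------------------------------

    @property
    def link(self) -> lk.LinkSpec:
        return self.model.link

    @property
    def data(self) -> BinaryDataset:
        return self.model.data

    @property
    def param_names(self) -> list[str]:
        return self.data.param_names(self.link.has_shape)

    @property
    def beta_mean(self) -> np.ndarray:
        return self.draws.beta.mean(axis=0)

    @property
    def delta_mean(self) -> float | None:
        return None if self.draws.delta is None else float(self.draws.delta.mean())

    @property
    def lam_mean(self) -> float | None:
        """Posterior mean of λ = exp(δ) (mean of exp, not exp of mean)."""
        return None if self.draws.delta is None else float(np.exp(self.draws.delta).mean())

    # -- diagnostics --------------------------------------------------------

    def _param_matrix(self) -> np.ndarray:
        cols = [self.draws.beta]
        if self.draws.delta is not None:
            cols.append(self.draws.delta[:, None])
        return np.hstack(cols)

    @property
    def rhat(self) -> dict[str, float]:
        """Split R-hat per parameter (δ reported under 'lambda')."""
        if self._rhat is None:
            import arviz as az

            c, d = self.chain_shape
            mat = self._param_matrix().reshape(c, d, -1)
            rh = az.rhat(az.convert_to_dataset(mat))["x"].values
            self._rhat = dict(zip(self.param_names, map(float, rh)))
        return self._rhat

    @property
    def converged(self) -> bool:
        return max(self.rhat.values()) <= RHAT_FAIL

    @property
    def n_divergent(self) -> int:
        return int(sum(d.n_divergent for d in self.sampler_diagnostics))

    # -- summaries ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, SD, median, 5%/95% percentiles, R-hat.

        The λ row summarises the exp(δ) draws directly, so the reported mean
        is E[λ | y] rather than exp(E[δ | y]).
        """
        cols = [self.draws.beta.T]
        if self.draws.delta is not None:
            cols.append(np.exp(self.draws.delta)[None, :])
        rows = []
        for name, draws in zip(self.param_names, np.vstack(cols)):
            q5, q50, q95 = np.percentile(draws, [5, 50, 95])
            rows.append(
                {
                    "parameter": name,
                    "mean": draws.mean(),
                    "sd": draws.std(ddof=1),
                    "median": q50,
                    "p5": q5,
                    "p95": q95,
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, prob: float = 0.95) -> pd.DataFrame:
        """Central credible intervals from posterior percentiles."""
        a = 100 * (1 - prob) / 2
        cols = [self.draws.beta.T]
        if self.draws.delta is not None:
            cols.append(np.exp(self.draws.delta)[None, :])
        out = {}
        for name, draws in zip(self.param_names, np.vstack(cols)):
            out[name] = np.percentile(draws, [a, 100 - a])
        return pd.DataFrame(out, index=["lower", "upper"]).T

    # -- prediction ---------------------------------------------------------

    def predict_prob(self, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior predictive success probabilities.

        Returns the S × n_new matrix of per-draw probabilities and its
        column means (the mean posterior predictive probability of each
        observation).
        """
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        if Xnew.shape[1] != self.data.k:
            raise ValueError(
                f"Xnew has {Xnew.shape[1]} columns, design has {self.data.k}"
            )
        mat = predictive_prob_matrix(self.draws.beta, self.draws.lam, Xnew, self.link)
        return mat, mat.mean(axis=0)

    def pointwise_loglik(self) -> np.ndarray:
        """Cached S × n matrix of pointwise log predictive densities."""
        if self._loglik is None:
            self._loglik = pointwise_loglik(
                self.draws.beta, self.draws.delta, self.data, self.link
            )
        return self._loglik

    # -- model comparison / diagnostics (delegates) -------------------------

    def deviance_summary(self):
        from .selection import deviance_summary

        return deviance_summary(self)

    def waic(self):
        from .selection import waic

        return waic(self.pointwise_loglik())

    def loo(self, method: str = "tis"):
        from .selection import psis_loo

        return psis_loo(self.pointwise_loglik(), method=method)

    def quantile_residuals(self, seed=0) -> np.ndarray:
        from .selection import quantile_residuals

        _, p_mean = self.predict_prob(self.data.X)
        return quantile_residuals(self.data.y, p_mean, seed=seed)

    def class_predictive_summary(self) -> pd.DataFrame:
        from .application import class_predictive_summary

        _, p_mean = self.predict_prob(self.data.X)
        return class_predictive_summary(p_mean, self.data.y)

    # -- export -------------------------------------------------------------

    def draws_to_csv(self, path) -> None:
        """One row per draw; parameter columns (λ on the exp scale) + chain."""
        df = pd.DataFrame(self.draws.beta, columns=self.param_names[: self.data.k])
        if self.draws.delta is not None:
            df["lambda"] = np.exp(self.draws.delta)
            df["delta"] = self.draws.delta
        df["chain"] = self.draws.chain_id
        df.to_csv(path, index=False)

    def report_to_json(self, path=None):
        """Fit report (summaries + diagnostics) as JSON text or file."""
        report = {
            "link": self.link.name,
            "n": self.data.n,
            "k": self.data.k,
            "chains": self.config.chains,
            "iterations": self.config.iterations,
            "warmup": self.config.warmup,
            "S": self.draws.S,
            "rhat": self.rhat,
            "n_divergent": self.n_divergent,
            "converged": self.converged,
            "summary": json.loads(self.summary().to_json(orient="index")),
        }
        text = json.dumps(report, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return report
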