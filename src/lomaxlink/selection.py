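"""Model comparison metrics and residual diagnostics.

Deviance-based criteria (DIC, EAIC, EBIC) use the posterior mean of the
deviance D̄ and the deviance at the posterior mean D̂ (with δ averaged on
the δ scale); fully Bayesian criteria (WAIC, LOO) are built from the S × n
matrix of pointwise log predictive densities.

LOO is estimated by importance sampling with per-observation ratios
r_i^{(s)} = 1 / p(y_i | θ^{(s)}) and truncated weights
w_i^{(s)} = min(r_i^{(s)}, √S · r̄_i); generalized-Pareto smoothing of the
weight tails (PSIS) is available as ``method="psis"``.  LOO is reported on
the deviance scale (−2·elpd) so its magnitude is directly comparable to
WAIC in the same table; smaller is better for every metric here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DevianceSummary",
    "WAICResult",
    "LOOResult",
    "deviance_summary",
    "waic",
    "psis_loo",
    "quantile_residuals",
    "comparison_table",
    "residual_plots",
]


@dataclass(frozen=True)
class DevianceSummary:
    D_bar: float
    D_hat: float
    rho_d: float
    DIC: float
    EAIC: float
    EBIC: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {
            "rho_d": self.rho_d, "D_bar": self.D_bar, "D_hat": self.D_hat,
            "DIC": self.DIC, "EAIC": self.EAIC, "EBIC": self.EBIC,
            "k": self.k, "n": self.n,
        }


@dataclass(frozen=True)
class WAICResult:
    lppd_hat: float
    p_waic: float
    WAIC: float


@dataclass(frozen=True)
class LOOResult:
    elpd: float
    LOO: float                    # deviance scale, -2 * elpd
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray | None = None


def deviance_summary(results) -> DevianceSummary:
    """D̄, D̂, ρ_d = D̄ − D̂, DIC = D̄ + ρ_d, EAIC = D̄ + 2k, EBIC = D̄ + k log n.

    D(θ) = −2 log L(θ); D̂ evaluates at the posterior means of β and δ.
    """
    from .model import log_likelihood

    draws = results.draws
    if draws.S < 2:
        raise ValueError("need at least 2 posterior draws")
    ll = results.pointwise_loglik().sum(axis=1)
    D_bar = float(np.mean(-2.0 * ll))
    D_hat = -2.0 * log_likelihood(
        results.beta_mean, results.delta_mean, results.data, results.link
    )
    rho_d = D_bar - D_hat
    k = results.data.k + results.link.n_shape
    n = results.data.n
    return DevianceSummary(
        D_bar=D_bar,
        D_hat=D_hat,
        rho_d=rho_d,
        DIC=D_bar + rho_d,
        EAIC=D_bar + 2 * k,
        EBIC=D_bar + k * np.log(n) if n else float("nan"),
        k=k,
        n=n,
    )


def waic(loglik: np.ndarray) -> WAICResult:
    """WAIC = −2(LPPD̂ − p̂_WAIC) from the S × n pointwise log-lik matrix.

    LPPD̂ = Σᵢ log(S⁻¹ Σₛ pᵢₛ);  p̂_WAIC = 2 Σᵢ (log-mean − mean-log).
    """
    loglik = np.atleast_2d(loglik)
    S = loglik.shape[0]
    if S < 1:
        raise ValueError("empty draw matrix")
    lme = _logmeanexp(loglik, axis=0)
    lppd = float(np.sum(lme))
    mean_log = loglik.mean(axis=0)
    p_waic = float(2.0 * np.sum(lme - mean_log))
    return WAICResult(lppd_hat=lppd, p_waic=p_waic, WAIC=-2.0 * (lppd - p_waic))


def _logmeanexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis) - np.log(a.shape[axis])


def _fit_gpd(x: np.ndarray) -> tuple[float, float]:
    """Generalized-Pareto fit on sorted exceedances.

    Zhang & Stephens (2009) quasi-Bayesian profile estimator; returns the
    shape k̂ (positive = heavy tail) and scale σ̂.
    """
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m_grid = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m_grid / (np.arange(1, m_grid + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        profile = n * (np.log(-(b / k)) - k - 1.0)
    profile[~np.isfinite(profile)] = -np.inf
    w = np.exp(profile - profile.max())
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post if b_post != 0 else np.nan
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(k * np.log1p(-p) * -1.0) / k


def _gpd_smooth_tail(r: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace the largest ~min(0.2·S, 3√S) ratios by GPD quantiles."""
    S = r.size
    M = int(np.ceil(min(0.2 * S, 3.0 * np.sqrt(S))))
    if M < 5 or M >= S:
        return r, np.nan
    order = np.argsort(r)  # tail indices order[-M:] are already ascending in r
    cutoff = r[order[-M - 1]]
    exceed = r[order[-M:]] - cutoff
    if np.ptp(exceed) <= 0:
        return r, np.nan
    k_hat, sigma = _fit_gpd(exceed)
    if not np.isfinite(k_hat) or not np.isfinite(sigma) or sigma <= 0:
        return r, np.nan
    q = (np.arange(1, M + 1) - 0.5) / M
    smoothed = cutoff + _gpd_quantile(q, k_hat, sigma)
    out = r.copy()
    out[order[-M:]] = np.minimum(smoothed, r.max())
    return out, float(k_hat)


def psis_loo(loglik: np.ndarray, method: str = "tis") -> LOOResult:
    """Leave-one-out elpd by (smoothed) truncated importance sampling.

    ``method='tis'`` truncates the raw ratios at √S times their mean — the
    estimator used throughout this package; ``method='psis'`` first smooths
    the largest ratios with a generalized-Pareto fit and records the
    tail-shape diagnostic k̂ per observation, then applies the same
    truncation.
    """
    from scipy.special import logsumexp

    if method not in ("tis", "psis"):
        raise ValueError("method must be 'tis' or 'psis'")
    loglik = np.atleast_2d(loglik)
    S, n = loglik.shape
    if S < 2:
        raise ValueError("need at least 2 draws")
    log_r = -loglik  # log importance ratios 1 / p(y_i | theta_s)
    # the estimator is invariant to per-observation rescaling of the weights
    r = np.exp(log_r - log_r.max(axis=0, keepdims=True))
    k_hats = None
    if method == "psis":
        k_hats = np.full(n, np.nan)
        r = r.copy()
        for i in range(n):
            r[:, i], k_hats[i] = _gpd_smooth_tail(r[:, i])
    w = np.minimum(r, np.sqrt(S) * r.mean(axis=0, keepdims=True))
    logw = np.log(w)
    elpd_i = logsumexp(loglik + logw, axis=0) - logsumexp(logw, axis=0)
    elpd = float(np.sum(elpd_i))
    return LOOResult(elpd=elpd, LOO=-2.0 * elpd, pointwise_elpd=elpd_i, pareto_k=k_hats)


def quantile_residuals(y: np.ndarray, p_hat: np.ndarray, seed=0) -> np.ndarray:
    """Randomized quantile residuals for Bernoulli responses.

    With fitted success probability p̂ᵢ, draw uᵢ uniformly on the cdf jump
    containing yᵢ — U(0, 1−p̂ᵢ) for a failure, U(1−p̂ᵢ, 1) for a success —
    and return Φ⁻¹(uᵢ).  Under a correctly specified model the residuals
    are i.i.d. standard normal.
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=y.size)
    lower = np.where(y == 1, 1.0 - p_hat, 0.0)
    upper = np.where(y == 1, 1.0, 1.0 - p_hat)
    v = lower + u * (upper - lower)
    v = np.clip(v, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(v)


def comparison_table(fits: list[tuple[str, object]]) -> pd.DataFrame:
    """One row per fitted model with every comparison metric.

    Columns: rho_d, D_bar, D_hat, DIC, EAIC, EBIC, LOO, WAIC, max_rhat,
    converged.  Metrics of non-converged fits (max R-hat above the failure
    threshold) are reported as NaN — the fit is listed but blanked, since
    criteria computed from non-stationary draws are not comparable.
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for label, res in fits:
        dev = res.deviance_summary()
        w = res.waic()
        loo = res.loo()
        max_rhat = max(res.rhat.values())
        row = {
            "model": label,
            "rho_d": dev.rho_d,
            "D_bar": dev.D_bar,
            "D_hat": dev.D_hat,
            "DIC": dev.DIC,
            "EAIC": dev.EAIC,
            "EBIC": dev.EBIC,
            "LOO": loo.LOO,
            "WAIC": w.WAIC,
            "max_rhat": max_rhat,
            "converged": res.converged,
        }
        if not res.converged:
            for key in ("rho_d", "D_bar", "D_hat", "DIC", "EAIC", "EBIC", "LOO", "WAIC"):
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def residual_plots(residuals: np.ndarray, path=None):
    """QQ-plot against the standard normal plus residual-vs-index panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    stats.probplot(residuals, dist="norm", plot=ax1)
    ax1.set_title("Normal QQ-plot of quantile residuals")
    ax2.scatter(np.arange(residuals.size), residuals, s=8, alpha=0.6)
    ax2.axhline(0.0, color="grey", lw=0.8)
    ax2.set_xlabel("observation index")
    ax2.set_ylabel("quantile residual")
    ax2.set_title("Residuals vs index")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
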