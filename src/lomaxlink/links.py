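"""Double-Lomax link family and classical binary-regression links.

The double Lomax (DLomax) distribution is the distribution of the ratio of
two i.i.d. standard Laplace variables: a symmetric, heavy-tailed law on the
real line with polynomial (Pareto-type) tails.  Skewness is introduced
through a single exponent ``lam`` (the asymmetry parameter λ) via the power
transform ``F_P(x) = G(x)**lam`` and the reverse-power transform
``F_RP(x) = 1 - G(-x)**lam``, where ``G`` is the standard DLomax cdf.
λ = 1 recovers the symmetric base distribution in both cases.

Used as link functions in Bernoulli regression, these cdfs map a linear
predictor η = x'β to a success probability p = F(η); the asymmetry lets the
link approach 0 and 1 at different rates, which is the mechanism by which
the family accommodates imbalanced class frequencies.

All functions are vectorised over ``x``/``eta`` and pure (no state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LinkSpec",
    "DLomaxParams",
    "CLASSICAL_LINKS",
    "POWER_LINKS",
    "LINK_NAMES",
    "dlomax_pdf",
    "dlomax_cdf",
    "dlomax_quantile",
    "pdlomax_pdf",
    "pdlomax_cdf",
    "pdlomax_quantile",
    "rpdlomax_pdf",
    "rpdlomax_cdf",
    "rpdlomax_quantile",
    "link_prob",
    "link_pdf",
    "link_dprob_dlam",
    "power_cauchy_prob",
    "random_variates",
    "PROB_CLIP",
]

CLASSICAL_LINKS = ("logit", "probit", "cauchit", "loglog", "cloglog")
#: links whose cdf carries the asymmetry exponent λ
POWER_LINKS = ("pdlomax", "rpdlomax")
LINK_NAMES = CLASSICAL_LINKS + ("dlomax",) + POWER_LINKS

#: probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before any log,
#: so extreme linear predictors cannot produce -inf log-likelihoods.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class DLomaxParams:
    """Location-scale parameters of the double Lomax distribution."""

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class LinkSpec:
    """A named link function, with asymmetry parameter λ where applicable.

    ``lam`` is required for the power links ('pdlomax', 'rpdlomax') when the
    spec is used to *evaluate* probabilities (simulation, prediction); when a
    power-link model is *fitted*, λ is treated as a free parameter and any
    value stored here is ignored by the sampler.
    """

    name: str
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.name not in LINK_NAMES:
            raise ValueError(
                f"unknown link {self.name!r}; choose one of {LINK_NAMES}"
            )
        if self.name in POWER_LINKS:
            if self.lam is not None and not self.lam > 0:
                raise ValueError(f"lam must be positive, got {self.lam}")
        elif self.lam is not None:
            raise ValueError(f"link {self.name!r} takes no asymmetry parameter")

    @property
    def has_shape(self) -> bool:
        """Whether this link carries a free asymmetry parameter."""
        return self.name in POWER_LINKS

    @property
    def n_shape(self) -> int:
        return 1 if self.has_shape else 0


def _as_spec(link: "LinkSpec | str") -> LinkSpec:
    return LinkSpec(link) if isinstance(link, str) else link


# ---------------------------------------------------------------------------
# double Lomax base distribution
# ---------------------------------------------------------------------------

def dlomax_pdf(x, params: DLomaxParams | None = None):
    """Density g(x) = 1 / (2 σ (1 + |x - μ|/σ)²)."""
    params = params or DLomaxParams()
    z = (np.asarray(x, dtype=float) - params.mu) / params.sigma
    return 0.5 / (params.sigma * (1.0 + np.abs(z)) ** 2)


def dlomax_cdf(x, params: DLomaxParams | None = None):
    """Piecewise cdf: 1/(2(1+(μ−x)/σ)) for x ≤ μ, 1 − 1/(2(1+(x−μ)/σ)) above.

    Both branches give 1/2 at x = μ; the x ≤ μ branch is used at the kink.
    """
    params = params or DLomaxParams()
    z = (np.asarray(x, dtype=float) - params.mu) / params.sigma
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(z <= 0, 0.5 / (1.0 - z), 1.0 - 0.5 / (1.0 + z))
    # limits at +-inf
    out = np.where(np.isneginf(z), 0.0, out)
    out = np.where(np.isposinf(z), 1.0, out)
    return out if out.ndim else float(out)


def dlomax_quantile(p, params: DLomaxParams | None = None):
    """Inverse of the standard-form cdf (closed form on each branch)."""
    params = params or DLomaxParams()
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    z = np.where(p <= 0.5, 1.0 - 0.5 / p, 0.5 / (1.0 - p) - 1.0)
    out = params.mu + params.sigma * z
    return out if out.ndim else float(out)


def _log_G(x):
    """log of the standard DLomax cdf, stable in both tails."""
    x = np.asarray(x, dtype=float)
    return np.where(
        x <= 0,
        np.log(0.5) - np.log1p(-np.minimum(x, 0.0)),
        np.log1p(-0.5 / (1.0 + np.maximum(x, 0.0))),
    )


def _check_lam(lam: float) -> float:
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    return float(lam)


# ---------------------------------------------------------------------------
# power double Lomax (PDLomax): F_P(x) = G(x)**lam
# ---------------------------------------------------------------------------

def pdlomax_cdf(x, lam: float):
    """F_P(x|λ) = [G(x)]^λ, computed as exp(λ·log G(x))."""
    lam = _check_lam(lam)
    x = np.asarray(x, dtype=float)
    out = np.exp(lam * _log_G(x))
    out = np.where(np.isposinf(x), 1.0, np.where(np.isneginf(x), 0.0, out))
    return out if out.ndim else float(out)


def pdlomax_pdf(x, lam: float):
    """f_P(x|λ) = λ g(x) [G(x)]^{λ−1}."""
    lam = _check_lam(lam)
    x = np.asarray(x, dtype=float)
    out = lam * dlomax_pdf(x) * np.exp((lam - 1.0) * _log_G(x))
    return out if out.ndim else float(out)


def pdlomax_quantile(p, lam: float):
    """x = G⁻¹(p^{1/λ})."""
    lam = _check_lam(lam)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    out = dlomax_quantile(np.exp(np.log(p) / lam))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# reverse power double Lomax (RPDLomax): F_RP(x) = 1 - G(-x)**lam
# ---------------------------------------------------------------------------

def rpdlomax_cdf(x, lam: float):
    """F_RP(x|λ) = 1 − [G(−x)]^λ (reflection of the power transform)."""
    lam = _check_lam(lam)
    x = np.asarray(x, dtype=float)
    out = -np.expm1(lam * _log_G(-x))
    out = np.where(np.isposinf(x), 1.0, np.where(np.isneginf(x), 0.0, out))
    return out if out.ndim else float(out)


def rpdlomax_pdf(x, lam: float):
    """f_RP(x|λ) = λ g(−x) [G(−x)]^{λ−1} = f_P(−x|λ)."""
    return pdlomax_pdf(-np.asarray(x, dtype=float), lam)


def rpdlomax_quantile(p, lam: float):
    """x = −G⁻¹((1−p)^{1/λ})."""
    lam = _check_lam(lam)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    out = -dlomax_quantile(np.exp(np.log1p(-p) / lam))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# generic link interface
# ---------------------------------------------------------------------------

def _classical_cdf(name: str, eta):
    eta = np.asarray(eta, dtype=float)
    if name == "logit":
        return stats.logistic.cdf(eta)
    if name == "probit":
        return stats.norm.cdf(eta)
    if name == "cauchit":
        return stats.cauchy.cdf(eta)
    if name == "loglog":
        # p = exp(-exp(-eta)), the Gumbel (max) cdf
        return np.exp(-np.exp(-eta))
    if name == "cloglog":
        # p = 1 - exp(-exp(eta)), the complementary log-log convention
        return -np.expm1(-np.exp(eta))
    raise ValueError(f"unknown classical link {name!r}")


def _classical_pdf(name: str, eta):
    eta = np.asarray(eta, dtype=float)
    if name == "logit":
        return stats.logistic.pdf(eta)
    if name == "probit":
        return stats.norm.pdf(eta)
    if name == "cauchit":
        return stats.cauchy.pdf(eta)
    if name == "loglog":
        return np.exp(-eta - np.exp(-eta))
    if name == "cloglog":
        return np.exp(eta - np.exp(eta))
    raise ValueError(f"unknown classical link {name!r}")


def link_prob(eta, link: LinkSpec | str, lam: float | None = None, clip: bool = True):
    """Success probability p = F(η) for any supported link.

    ``lam`` overrides the value stored on the LinkSpec (used by the sampler,
    where λ is a free parameter).  Probabilities are clipped away from 0 and
    1 by :data:`PROB_CLIP` unless ``clip=False``.
    """
    spec = _as_spec(link)
    eta = np.asarray(eta, dtype=float)
    if spec.name == "dlomax":
        p = dlomax_cdf(eta)
    elif spec.name in POWER_LINKS:
        lam_eff = lam if lam is not None else spec.lam
        if lam_eff is None:
            raise ValueError(f"link {spec.name!r} requires lam")
        p = pdlomax_cdf(eta, lam_eff) if spec.name == "pdlomax" else rpdlomax_cdf(eta, lam_eff)
    else:
        p = _classical_cdf(spec.name, eta)
    p = np.asarray(p, dtype=float)
    if clip:
        p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return p if p.ndim else float(p)


def link_pdf(eta, link: LinkSpec | str, lam: float | None = None):
    """Density F'(η) of the link distribution (dp/dη)."""
    spec = _as_spec(link)
    eta = np.asarray(eta, dtype=float)
    if spec.name == "dlomax":
        out = dlomax_pdf(eta)
    elif spec.name in POWER_LINKS:
        lam_eff = lam if lam is not None else spec.lam
        if lam_eff is None:
            raise ValueError(f"link {spec.name!r} requires lam")
        out = pdlomax_pdf(eta, lam_eff) if spec.name == "pdlomax" else rpdlomax_pdf(eta, lam_eff)
    else:
        out = _classical_pdf(spec.name, eta)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def link_dprob_dlam(eta, link: LinkSpec | str, lam: float):
    """∂p/∂λ for the power links (zero for all λ-free links).

    PDLomax:  ∂/∂λ G^λ = G^λ log G.
    RPDLomax: ∂/∂λ (1 − G(−η)^λ) = −G(−η)^λ log G(−η).
    """
    spec = _as_spec(link)
    eta = np.asarray(eta, dtype=float)
    if spec.name == "pdlomax":
        lg = _log_G(eta)
        out = np.exp(lam * lg) * lg
    elif spec.name == "rpdlomax":
        lg = _log_G(-eta)
        out = -np.exp(lam * lg) * lg
    else:
        out = np.zeros_like(eta)
    return out if out.ndim else float(out)


def link_quantile(p, link: LinkSpec | str, lam: float | None = None):
    """Inverse link F⁻¹(p), used for inverse-transform sampling."""
    spec = _as_spec(link)
    p = np.asarray(p, dtype=float)
    if spec.name == "dlomax":
        return dlomax_quantile(p)
    if spec.name in POWER_LINKS:
        lam_eff = lam if lam is not None else spec.lam
        if lam_eff is None:
            raise ValueError(f"link {spec.name!r} requires lam")
        fn = pdlomax_quantile if spec.name == "pdlomax" else rpdlomax_quantile
        return fn(p, lam_eff)
    if spec.name == "logit":
        return stats.logistic.ppf(p)
    if spec.name == "probit":
        return stats.norm.ppf(p)
    if spec.name == "cauchit":
        return stats.cauchy.ppf(p)
    if spec.name == "loglog":
        return -np.log(-np.log(p))
    if spec.name == "cloglog":
        return np.log(-np.log1p(-p))
    raise ValueError(f"unknown link {spec.name!r}")


def power_cauchy_prob(eta, lam: float):
    """Power Cauchy response p = (arctan(η)/π + 1/2)^λ.

    This is the exponentiated cauchit link used as the data-generating
    mechanism in the misspecification experiment; it is deliberately outside
    the candidate link family.
    """
    lam = _check_lam(lam)
    eta = np.asarray(eta, dtype=float)
    out = np.exp(lam * np.log(np.arctan(eta) / np.pi + 0.5))
    return out if out.ndim else float(out)


def random_variates(link: LinkSpec | str, n: int, seed, lam: float | None = None):
    """Draw ``n`` variates from the link distribution by inverse transform.

    ``seed`` may be an int, a ``numpy.random.Generator`` or a SeedSequence;
    the same seed yields an identical stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return np.asarray(link_quantile(u, link, lam=lam), dtype=float)
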