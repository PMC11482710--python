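"""No-U-Turn Sampler with dual-averaging step-size adaptation.

A self-contained gradient-based MCMC engine for the small, smooth posteriors
this package fits (a handful of regression coefficients plus, for the power
links, one transformed asymmetry parameter).  The implementation follows the
standard recipe: recursive doubling of a leapfrog trajectory with a slice
variable, stopping on the U-turn criterion; step size adapted during warmup
by dual averaging toward a target acceptance statistic; a diagonal mass
matrix estimated from the middle of the warmup phase.

Nothing here is specific to binary regression — the engine takes an
arbitrary ``logp_and_grad`` callable — but it is tuned for low dimension:
trees are built recursively (max depth 10, well within Python limits) and no
attempt is made at vectorising across chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["NUTSDiagnostics", "nuts_sample", "SamplingError"]

_MAX_DEPTH = 10
_DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent transition


class SamplingError(RuntimeError):
    """Raised when a chain cannot produce finite proposals."""


@dataclass
class NUTSDiagnostics:
    """Per-chain sampler health indicators."""

    step_size: float
    n_divergent: int
    mean_accept: float
    mass_diag: np.ndarray = field(repr=False, default=None)


def _leapfrog(logp_and_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    logp, grad = logp_and_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * np.dot(p, inv_mass * p)


def _find_reasonable_epsilon(logp_and_grad, x0, rng, inv_mass):
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 1/2."""
    eps = 1.0
    logp0, grad0 = logp_and_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, inv_mass)
    h0 = logp0 - _kinetic(p0, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** a
        _, p1, logp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


def _build_tree(logp_and_grad, x, p, grad, logu, v, depth, eps, h0, inv_mass, rng, stats):
    """Recursive doubling; returns the subtree summary.

    Returns (x_minus, p_minus, grad_minus, x_plus, p_plus, grad_plus,
             x_prop, logp_prop, grad_prop, n_valid, keep_going).
    """
    if depth == 0:
        x1, p1, logp1, grad1 = _leapfrog(logp_and_grad, x, p, grad, v * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        n_valid = int(logu <= h1)
        diverged = logu - _DIVERGENCE_THRESHOLD >= h1
        if diverged:
            stats["divergent"] = True
        stats["sum_accept"] += min(1.0, np.exp(min(0.0, h1 - h0)))
        stats["n_accept"] += 1
        return x1, p1, grad1, x1, p1, grad1, x1, logp1, grad1, n_valid, not diverged
    # build left/right halves
    (xm, pm, gm, xp, pp, gp, xprop, lprop, gprop, n1, cont) = _build_tree(
        logp_and_grad, x, p, grad, logu, v, depth - 1, eps, h0, inv_mass, rng, stats
    )
    if cont:
        if v == -1:
            (xm, pm, gm, _, _, _, xprop2, lprop2, gprop2, n2, cont2) = _build_tree(
                logp_and_grad, xm, pm, gm, logu, v, depth - 1, eps, h0, inv_mass, rng, stats
            )
        else:
            (_, _, _, xp, pp, gp, xprop2, lprop2, gprop2, n2, cont2) = _build_tree(
                logp_and_grad, xp, pp, gp, logu, v, depth - 1, eps, h0, inv_mass, rng, stats
            )
        if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
            xprop, lprop, gprop = xprop2, lprop2, gprop2
        dx = xp - xm
        cont = (
            cont2
            and np.dot(dx, inv_mass * pm) >= 0
            and np.dot(dx, inv_mass * pp) >= 0
        )
        n1 += n2
    return xm, pm, gm, xp, pp, gp, xprop, lprop, gprop, n1, cont


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = _MAX_DEPTH,
) -> tuple[np.ndarray, NUTSDiagnostics]:
    """Run one NUTS chain; returns post-warmup draws and diagnostics.

    ``n_iter`` counts total iterations including the ``warmup`` ones, so the
    returned array has ``n_iter - warmup`` rows.
    """
    if warmup >= n_iter:
        raise ValueError("warmup must be smaller than n_iter")
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    logp, grad = logp_and_grad(x)
    if not np.isfinite(logp):
        raise SamplingError("initial point has non-finite log posterior")

    eps = _find_reasonable_epsilon(logp_and_grad, x, rng, inv_mass)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-matrix estimation window (middle portion of warmup)
    w_start, w_end = int(0.25 * warmup), max(int(0.75 * warmup), int(0.25 * warmup) + 1)
    window: list[np.ndarray] = []

    draws = np.empty((n_iter - warmup, dim))
    n_divergent = 0
    accept_hist: list[float] = []

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(p0, inv_mass)
        # slice variable (log scale)
        logu = h0 + np.log(rng.uniform())
        xm = xp = x
        pm = pp = p0
        gm = gp = grad
        depth, n_valid, cont = 0, 1, True
        stats = {"sum_accept": 0.0, "n_accept": 0, "divergent": False}
        while cont and depth < max_depth:
            v = -1 if rng.uniform() < 0.5 else 1
            if v == -1:
                (xm, pm, gm, _, _, _, xprop, lprop, gprop, n_new, cont2) = _build_tree(
                    logp_and_grad, xm, pm, gm, logu, v, depth, eps, h0, inv_mass, rng, stats
                )
            else:
                (_, _, _, xp, pp, gp, xprop, lprop, gprop, n_new, cont2) = _build_tree(
                    logp_and_grad, xp, pp, gp, logu, v, depth, eps, h0, inv_mass, rng, stats
                )
            if cont2 and n_new > 0 and rng.uniform() < min(1.0, n_new / n_valid):
                x, logp, grad = xprop, lprop, gprop
            n_valid += n_new
            dx = xp - xm
            cont = (
                cont2
                and np.dot(dx, inv_mass * pm) >= 0
                and np.dot(dx, inv_mass * pp) >= 0
            )
            depth += 1
        if stats["divergent"]:
            n_divergent += 1
        accept_stat = stats["sum_accept"] / max(stats["n_accept"], 1)

        if it < warmup:
            # dual averaging toward the target acceptance statistic
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_start <= it < w_end:
                window.append(x.copy())
            if it == w_end - 1 and len(window) >= 5:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                n_w = len(window)
                # regularised variance estimate (shrunk toward unit scale)
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                eps = _find_reasonable_epsilon(logp_and_grad, x, rng, inv_mass)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
        else:
            if it == warmup:
                eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0.0 else eps
            accept_hist.append(accept_stat)
            draws[it - warmup] = x

    diag = NUTSDiagnostics(
        step_size=eps,
        n_divergent=n_divergent,
        mean_accept=float(np.mean(accept_hist)) if accept_hist else float("nan"),
        mass_diag=inv_mass,
    )
    return draws, diag
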