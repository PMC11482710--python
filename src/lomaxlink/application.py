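"""End-to-end application helpers: point prediction on the raw covariate
scale, covariate effect curves, and class-conditional predictive summaries.

These operate on *point estimates* (posterior means of β and λ) plus the
standardization constants stored at ingestion time, so a fitted model can be
interrogated on the original measurement scale — e.g. "what is the success
probability when this covariate equals v and every other covariate sits at
its sample mean?".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .links import LinkSpec, link_prob

__all__ = [
    "predict_at",
    "effect_curve",
    "class_predictive_summary",
]


def _eta_at(beta_point, covariate_names, covariate_values, standardization):
    beta_point = np.asarray(beta_point, dtype=float)
    if beta_point.size != len(covariate_names) + 1:
        raise ValueError(
            f"beta has {beta_point.size} entries for {len(covariate_names)} covariates"
        )
    eta = beta_point[0]
    for j, name in enumerate(covariate_names):
        value = covariate_values.get(name, "mean")
        if value == "mean" or value is None:
            z = 0.0  # at its mean a standardized covariate is exactly 0
        else:
            if name not in standardization:
                raise ValueError(f"no standardization constants stored for {name!r}")
            mean, sd = standardization[name]
            z = (float(value) - mean) / sd
        eta += beta_point[j + 1] * z
    return float(eta)


def predict_at(
    beta_point,
    lam_point: float | None,
    link: LinkSpec | str,
    covariate_values: dict,
    covariate_names: list[str],
    standardization: dict,
) -> float:
    """Success probability at raw covariate values, others at their means.

    ``covariate_values`` maps covariate name -> raw value; any covariate not
    listed (or listed as ``"mean"``) is held at its sample mean, which is 0
    on the standardized scale.  ``beta_point`` and ``lam_point`` are the
    posterior-mean point estimates.
    """
    unknown = set(covariate_values) - set(covariate_names)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    eta = _eta_at(beta_point, covariate_names, covariate_values, standardization)
    return float(link_prob(eta, link, lam=lam_point))


def effect_curve(
    beta_point,
    lam_point: float | None,
    link: LinkSpec | str,
    covariate: str,
    grid,
    covariate_names: list[str],
    standardization: dict,
) -> pd.DataFrame:
    """Probability of success as one covariate sweeps a grid of raw values,
    holding every other covariate at its sample mean."""
    if covariate not in covariate_names:
        raise ValueError(f"unknown covariate {covariate!r}")
    grid = np.asarray(grid, dtype=float)
    probs = [
        predict_at(
            beta_point, lam_point, link, {covariate: v},
            covariate_names, standardization,
        )
        for v in grid
    ]
    return pd.DataFrame({covariate: grid, "prob": probs})


def class_predictive_summary(p_mean: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Six-number summaries of mean predictive probabilities by observed class.

    Rows 'success' (y=1) and 'failure' (y=0); columns min, Q1, median, mean,
    Q3, max.  A well-separating classifier puts the success row well above
    the failure row.  If only one class is present, only that row is
    returned (with a warning).
    """
    p_mean = np.asarray(p_mean, dtype=float)
    y = np.asarray(y, dtype=float)
    if p_mean.shape != y.shape:
        raise ValueError("p_mean and y must have the same length")
    rows = {}
    for label, mask in (("success", y == 1), ("failure", y == 0)):
        if not mask.any():
            warnings.warn(f"no observations in class {label!r}", stacklevel=2)
            continue
        p = p_mean[mask]
        q1, med, q3 = np.percentile(p, [25, 50, 75])
        rows[label] = {
            "min": p.min(), "q1": q1, "median": med,
            "mean": p.mean(), "q3": q3, "max": p.max(),
        }
    return pd.DataFrame(rows).T
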