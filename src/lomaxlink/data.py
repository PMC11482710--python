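"""Tabular ingestion: binary response datasets, standardization, screening.

The workflow mirrors common practice for regression on observational data:
covariates are z-scored in-sample (the standardization constants are kept so
predictions can be made on the raw scale), and pairs of nearly collinear
covariates are screened out before fitting, dropping from each offending
pair the member that is on average more correlated with everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "PreprocessReport",
    "load_csv",
    "correlation_screen",
    "standardize_value",
]


@dataclass
class BinaryDataset:
    """Binary response ``y`` plus design matrix ``X`` (intercept first).

    ``standardization`` maps covariate name -> (mean, sd) on the raw scale;
    empty when covariates entered unstandardized.
    """

    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.size} entries"
            )
        if self.y.size and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("response must contain only 0/1 values")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")
        if self.y.size and self.y.size < self.X.shape[1]:
            raise ValueError("need at least as many observations as parameters")
        if self.y.size and not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        if not self.covariate_names:
            self.covariate_names = [f"x{j}" for j in range(1, self.X.shape[1])]
        if len(self.covariate_names) != self.X.shape[1] - 1:
            raise ValueError("covariate_names must name every non-intercept column")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def success_rate(self) -> float:
        return float(self.y.mean()) if self.y.size else float("nan")

    @classmethod
    def empty(cls, k: int = 2) -> "BinaryDataset":
        """Zero-observation dataset (posterior = prior)."""
        return cls(np.empty(0), np.empty((0, k)), [f"x{j}" for j in range(1, k)])

    def param_names(self, shape: bool) -> list[str]:
        names = ["beta0"] + [f"beta{j + 1}" for j in range(len(self.covariate_names))]
        return names + (["lambda"] if shape else [])


@dataclass
class PreprocessReport:
    """What preprocessing did: dropped covariates and z-score constants."""

    dropped: list[dict] = field(default_factory=list)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped": self.dropped,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "correlated_pairs": [list(p) for p in self.correlated_pairs],
        }


def correlation_screen(
    df: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop one member of every covariate pair with |r| >= ``threshold``.

    The member dropped is the one with the larger mean absolute correlation
    with all other covariates (ties broken by column order, the later column
    being dropped).  Returns the reduced frame plus a report of the action.
    """
    report = PreprocessReport()
    cols = list(df.columns)
    if len(cols) < 2:
        return df, report
    corr = df.corr().to_numpy()
    mean_abs = (np.abs(corr).sum(axis=1) - 1.0) / max(len(cols) - 1, 1)
    drop: set[str] = set()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr[i, j]
            if abs(r) >= threshold:
                report.correlated_pairs.append((cols[i], cols[j], float(r)))
                if cols[i] in drop or cols[j] in drop:
                    continue
                # drop the member more correlated with the rest; later column on tie
                victim, partner = (
                    (cols[i], cols[j]) if mean_abs[i] > mean_abs[j] else (cols[j], cols[i])
                )
                drop.add(victim)
                report.dropped.append(
                    {"covariate": victim, "partner": partner, "r": float(r)}
                )
    return df.drop(columns=sorted(drop, key=cols.index)), report


def load_csv(
    path,
    response_column: str,
    standardize: bool = True,
    correlation_threshold: float | None = None,
) -> tuple[BinaryDataset, PreprocessReport]:
    """Read a CSV with a binary response and numeric covariates.

    Covariates are z-scored in-sample when ``standardize`` is true; an
    all-ones intercept column is prepended.  When ``correlation_threshold``
    is given, near-collinear covariates are screened out first.
    """
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ValueError(f"response column {response_column!r} not in {list(df.columns)}")
    if df.isna().any().any():
        raise ValueError("dataset contains missing values")
    y = df[response_column].to_numpy()
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError(f"response column {response_column!r} is not binary 0/1")
    covs = df.drop(columns=[response_column])
    if not all(np.issubdtype(dt, np.number) for dt in covs.dtypes):
        raise ValueError("all covariates must be numeric")

    report = PreprocessReport()
    if correlation_threshold is not None and covs.shape[1] >= 2:
        covs, report = correlation_screen(covs, threshold=correlation_threshold)

    Z = covs.to_numpy(dtype=float)
    constants: dict[str, tuple[float, float]] = {}
    if standardize:
        means = Z.mean(axis=0)
        sds = Z.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            bad = [covs.columns[i] for i in zero]
            raise ValueError(f"constant covariate(s) cannot be standardized: {bad}")
        Z = (Z - means) / sds
        constants = {
            name: (float(m), float(s))
            for name, m, s in zip(covs.columns, means, sds)
        }
    report.standardization = constants

    X = np.column_stack([np.ones(len(df)), Z])
    data = BinaryDataset(
        y=y.astype(float),
        X=X,
        covariate_names=list(covs.columns),
        standardization=constants,
    )
    return data, report


def standardize_value(value: float, name: str, constants: dict) -> float:
    """Map one raw covariate value to the z-scored scale used in fitting."""
    if name not in constants:
        raise ValueError(f"no standardization constants stored for {name!r}")
    mean, sd = constants[name]
    return (value - mean) / sd
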