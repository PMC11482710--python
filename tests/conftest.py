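"""Shared fixtures: a handful of fitted models reused across test modules.

The expensive Monte Carlo objects (a well-specified fit at n=2000, the
reduced-scale recovery and misspecification studies, a small fit with many
draws for leave-one-out work) are session-scoped so each is computed once.
"""

import warnings

import numpy as np
import pytest

from lomaxlink import (
    BernoulliLinkModel,
    LinkSpec,
    MisspecConfig,
    RecoveryConfig,
    misspec_study,
    recovery_study,
    simulate_binary,
)


@pytest.fixture(scope="session")
def rpdlomax_fit():
    """Well-specified RPDLomax(λ=2) fit at n=2000, β=(0,1), X~U(-3,3)."""
    data = simulate_binary(LinkSpec("rpdlomax", 2.0), (0.0, 1.0), 2000, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BernoulliLinkModel(data, "rpdlomax").fit(
            chains=4, iterations=600, warmup=300, seed=7
        )
    return res


@pytest.fixture(scope="session")
def logit_fit():
    """Well-specified logistic fit at n=2000."""
    data = simulate_binary("logit", (0.0, 1.0), 2000, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BernoulliLinkModel(data, "logit").fit(
            chains=4, iterations=600, warmup=300, seed=3
        )
    return res


@pytest.fixture(scope="session")
def small_logit_fit():
    """n=20 logistic fit with S=4000 draws, for leave-one-out comparisons."""
    data = simulate_binary("logit", (0.0, 1.0), 20, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BernoulliLinkModel(data, "logit").fit(
            chains=4, iterations=2000, warmup=1000, seed=5
        )
    return res


@pytest.fixture(scope="session")
def prior_only_fit():
    """Zero-observation fit: the posterior is exactly the prior."""
    from lomaxlink import BinaryDataset

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BernoulliLinkModel(BinaryDataset.empty(k=2), "rpdlomax").fit(
            chains=4, iterations=1500, warmup=500, seed=11
        )
    return res


@pytest.fixture(scope="session")
def recovery_report():
    """Reduced-scale parameter-recovery study (R=60 replicates).

    Same scenario grid as the full experiment — logistic, DLomax,
    PDLomax(λ=2), RPDLomax(λ=2) at n ∈ {500, 1000, 2000} with the short
    chain settings (4 chains, 200 iterations, 100 warmup) — at R=60
    rather than 100 to keep the suite within its time budget while leaving
    the coverage estimates precise enough to interpret (SE ≈ 0.03-0.04).
    """
    cfg = RecoveryConfig(R=60, seed=314)
    summary, replicates = recovery_study(cfg)
    return cfg, summary, replicates


@pytest.fixture(scope="session")
def misspec_report():
    """Reduced-scale misspecification study: λ=0.5, n=1000, R=20,
    PDLomax vs the logistic baseline."""
    cfg = MisspecConfig(
        lambda_grid=(0.5,),
        n=1000,
        R=20,
        candidate_links=("logit", "pdlomax"),
        seed=2718,
    )
    summary, replicates = misspec_study(cfg)
    return cfg, summary, replicates
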