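"""Comparison metrics: identities, hand-computed cases, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lomaxlink import (
    comparison_table,
    psis_loo,
    quantile_residuals,
    waic,
)
from lomaxlink.selection import DevianceSummary


class TestDeviance:
    def test_identical_draws_have_zero_effective_parameters(self, rpdlomax_fit):
        """Collapse all draws onto one point: D̄ = D̂, ρ_d = 0, DIC = D̄."""
        import copy

        res = copy.copy(rpdlomax_fit)
        res.model = rpdlomax_fit.model
        from lomaxlink.model import PosteriorDraws

        one_beta = np.tile(rpdlomax_fit.beta_mean, (4, 1))
        one_delta = np.full(4, rpdlomax_fit.delta_mean)
        res.draws = PosteriorDraws(one_beta, one_delta, np.array([0, 0, 1, 1]))
        res._loglik = None
        dev = res.deviance_summary()
        assert dev.rho_d == pytest.approx(0.0, abs=1e-9)
        assert dev.DIC == pytest.approx(dev.D_bar, abs=1e-9)

    def test_dbar_is_average_of_per_draw_deviances(self, rpdlomax_fit):
        dev = rpdlomax_fit.deviance_summary()
        ll = rpdlomax_fit.pointwise_loglik().sum(axis=1)
        assert dev.D_bar == pytest.approx(np.mean(-2 * ll))

    def test_metric_identities(self, rpdlomax_fit):
        """DIC/EAIC/EBIC identities hold to numerical precision."""
        dev = rpdlomax_fit.deviance_summary()
        assert dev.rho_d == pytest.approx(dev.D_bar - dev.D_hat, abs=1e-10)
        assert dev.DIC == pytest.approx(dev.D_bar + dev.rho_d, abs=1e-10)
        assert dev.EAIC == pytest.approx(dev.D_bar + 2 * dev.k, abs=1e-10)
        assert dev.EBIC == pytest.approx(dev.D_bar + dev.k * np.log(dev.n), abs=1e-10)
        # EAIC - EBIC = k (2 - log n), an arithmetic identity
        assert dev.EAIC - dev.EBIC == pytest.approx(dev.k * (2 - np.log(dev.n)))


class TestWAIC:
    def test_identical_draws_single_observation(self):
        """One observation, all draws at p=0.5, y=1."""
        ll = np.full((6, 1), np.log(0.5))
        w = waic(ll)
        assert w.lppd_hat == pytest.approx(np.log(0.5))
        assert w.p_waic == pytest.approx(0.0, abs=1e-12)
        assert w.WAIC == pytest.approx(-2 * np.log(0.5))  # = 1.386

    def test_two_draw_hand_computation(self):
        """y=1 with draws p ∈ {0.4, 0.6}: lppd = log 0.5 and the penalty is
        twice the Jensen gap between log-mean and mean-log."""
        ll = np.log(np.array([[0.4], [0.6]]))
        w = waic(ll)
        assert w.lppd_hat == pytest.approx(np.log(0.5))
        expected_p = 2 * (np.log(0.5) - (np.log(0.4) + np.log(0.6)) / 2)
        assert w.p_waic == pytest.approx(expected_p)
        assert w.WAIC == pytest.approx(-2 * (w.lppd_hat - w.p_waic), abs=1e-12)

    def test_waic_improves_when_draws_concentrate_on_truth(self):
        y = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        rng = np.random.default_rng(0)

        def ll_matrix(p_center, spread):
            p = np.clip(p_center[None, :] + spread * rng.normal(size=(200, 5)), 0.01, 0.99)
            return y[None, :] * np.log(p) + (1 - y[None, :]) * np.log(1 - p)

        good = waic(ll_matrix(np.where(y == 1, 0.9, 0.1), 0.02))
        bad = waic(ll_matrix(np.full(5, 0.5), 0.02))
        assert good.WAIC < bad.WAIC

    def test_p_waic_nonnegative(self, rpdlomax_fit):
        assert rpdlomax_fit.waic().p_waic >= -1e-10


class TestLOO:
    def test_identical_draws_reduce_to_plain_deviance(self):
        """With a degenerate posterior, LOO = −2 Σ log p(y_i | θ)."""
        ll_row = np.log(np.array([0.7, 0.2, 0.9]))
        ll = np.tile(ll_row, (8, 1))
        res = psis_loo(ll)
        assert res.LOO == pytest.approx(-2 * ll_row.sum(), abs=1e-10)

    def test_elpd_below_lppd(self, rpdlomax_fit, small_logit_fit):
        """Leaving an observation out can only lower its predictive density."""
        for fit in (rpdlomax_fit, small_logit_fit):
            loo = fit.loo()
            assert loo.elpd <= waic(fit.pointwise_loglik()).lppd_hat

    def test_loo_identity_and_scale(self, rpdlomax_fit):
        loo = rpdlomax_fit.loo()
        assert loo.LOO == pytest.approx(-2 * loo.elpd, abs=1e-10)
        assert loo.pointwise_elpd.sum() == pytest.approx(loo.elpd, abs=1e-10)

    def test_waic_and_loo_agree_on_well_specified_fit(self, rpdlomax_fit):
        """At n=2000 with a well-specified model the two fully Bayesian
        criteria agree to well under 1%."""
        loo = rpdlomax_fit.loo().LOO
        w = rpdlomax_fit.waic().WAIC
        assert abs(loo - w) / abs(w) < 0.01

    def test_truncated_and_pareto_smoothed_variants_agree(self, small_logit_fit):
        ll = small_logit_fit.pointwise_loglik()
        tis = psis_loo(ll, method="tis")
        psis = psis_loo(ll, method="psis")
        assert abs(tis.elpd - psis.elpd) / abs(tis.elpd) < 0.01
        assert psis.pareto_k is not None

    def test_matches_arviz_psis_loo(self, small_logit_fit):
        """Independent cross-check against the reference PSIS-LOO."""
        az = pytest.importorskip("arviz")
        ll = small_logit_fit.pointwise_loglik()
        c, d = small_logit_fit.chain_shape
        idata = az.from_dict(
            posterior={"beta": small_logit_fit.draws.beta.reshape(c, d, -1)},
            log_likelihood={"y": ll.reshape(c, d, -1)},
        )
        ref = az.loo(idata, pointwise=False)
        ours = psis_loo(ll, method="psis")
        assert ours.elpd == pytest.approx(float(ref.elpd_loo), rel=0.01)

    def test_method_validation(self):
        with pytest.raises(ValueError):
            psis_loo(np.zeros((4, 2)), method="exact")
        with pytest.raises(ValueError):
            psis_loo(np.zeros((1, 2)))


class TestQuantileResiduals:
    def test_success_at_half_probability_is_positive(self):
        y = np.ones(500)
        r = quantile_residuals(y, np.full(500, 0.5), seed=3)
        assert np.all(r > 0)

    def test_failure_at_half_probability_is_negative(self):
        y = np.zeros(500)
        r = quantile_residuals(y, np.full(500, 0.5), seed=3)
        assert np.all(r < 0)

    def test_seed_reproducibility(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        p = np.array([0.2, 0.7, 0.9, 0.4])
        np.testing.assert_array_equal(
            quantile_residuals(y, p, seed=11), quantile_residuals(y, p, seed=11)
        )
        assert not np.array_equal(
            quantile_residuals(y, p, seed=11), quantile_residuals(y, p, seed=12)
        )

    def test_normality_under_true_model(self):
        """Residuals built from the *true* success probabilities are exactly
        standard normal in distribution."""
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.uniform(size=5000) < p).astype(float)
        r = quantile_residuals(y, p, seed=1)
        assert stats.kstest(r, "norm").pvalue > 0.01


class _StubFit:
    """Minimal results-like object for table assembly tests."""

    def __init__(self, loglik, k=2, n=None, rhat=1.0):
        self._ll = np.atleast_2d(loglik)
        self._k = k
        self._n = n or self._ll.shape[1]
        self._rhat = rhat

    def pointwise_loglik(self):
        return self._ll

    def deviance_summary(self):
        ll = self._ll.sum(axis=1)
        D_bar = float(np.mean(-2 * ll))
        D_hat = float(-2 * ll.max())  # stand-in plug-in deviance
        return DevianceSummary(
            D_bar=D_bar, D_hat=D_hat, rho_d=D_bar - D_hat,
            DIC=2 * D_bar - D_hat, EAIC=D_bar + 2 * self._k,
            EBIC=D_bar + self._k * np.log(self._n), k=self._k, n=self._n,
        )

    def waic(self):
        return waic(self._ll)

    def loo(self):
        return psis_loo(self._ll)

    @property
    def rhat(self):
        return {"beta0": self._rhat}

    @property
    def converged(self):
        return self._rhat <= 1.1


class TestComparisonTable:
    def test_uniformly_better_model_wins_every_metric(self):
        rng = np.random.default_rng(5)
        base = np.log(rng.uniform(0.3, 0.7, size=(50, 30)))
        better = base + 0.4  # uniformly higher pointwise log-likelihood
        table = comparison_table([("worse", _StubFit(base)), ("better", _StubFit(better))])
        for col in ("D_bar", "DIC", "EAIC", "EBIC", "LOO", "WAIC"):
            assert table.loc["better", col] < table.loc["worse", col]

    def test_identities_recheck_in_rows(self, rpdlomax_fit, logit_fit):
        table = comparison_table([("rpdlomax", rpdlomax_fit), ("logit", logit_fit)])
        for _, row in table.iterrows():
            assert row["DIC"] == pytest.approx(row["D_bar"] + row["rho_d"], abs=1e-8)

    def test_non_converged_fit_is_blanked(self):
        rng = np.random.default_rng(2)
        ll = np.log(rng.uniform(0.3, 0.7, size=(20, 10)))
        table = comparison_table(
            [("ok", _StubFit(ll)), ("bad", _StubFit(ll, rhat=1.5))]
        )
        assert not table.loc["bad", "converged"]
        assert np.isnan(table.loc["bad", "WAIC"])
        assert np.isfinite(table.loc["ok", "WAIC"])

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        ll = np.log(rng.uniform(0.3, 0.7, size=(20, 10)))
        table = comparison_table([("m", _StubFit(ll))])
        path = tmp_path / "cmp.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col="model")
        pd.testing.assert_frame_equal(table, back, check_dtype=False)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            comparison_table([])


def test_well_specified_fit_residuals_look_normal(rpdlomax_fit):
    """QQ agreement with N(0,1) for residuals from a correctly specified fit."""
    r = rpdlomax_fit.quantile_residuals(seed=123)
    assert stats.kstest(r, "norm").pvalue > 0.01
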