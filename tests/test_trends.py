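"""Trend estimation, AR(1) fitting, surrogate generation, p-values, ensembles."""

import numpy as np
import pandas as pd
import pytest

from marshpace import (
    AR1Model,
    LevelSeries,
    correlation_p_value,
    fit_ar1,
    ols_trend,
    pooled_point_rate,
    simulate_surrogates,
    trend_ensemble,
    trend_p_value,
    white_noise_surrogates,
)
from marshpace.series import decimal_years, slope_weights

from conftest import monthly_series


class TestOlsTrend:
    def test_exact_line_rate_mm_per_year(self):
        # 15.7 mm rise over one year of monthly data
        t = np.arange(13.0)
        ens = ols_trend(monthly_series(0.0157 * t / 12))
        assert ens.rate == pytest.approx(15.7, abs=1e-9)

    def test_constant_series(self):
        ens = ols_trend(monthly_series(np.full(24, 0.8)))
        assert ens.rate == pytest.approx(0.0, abs=1e-12)
        assert ens.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_oracle(self):
        # independent normal-equations solution on a small irregular series
        import statsmodels.api as sm

        vals = np.array([0.0, 2.0, 1.0, 3.0, 5.0]) / 1000.0  # mm -> m
        s = monthly_series(vals)
        t = s.times_decimal()
        fit = sm.OLS(vals, sm.add_constant(t)).fit()
        ens = ols_trend(s)
        assert ens.rate == pytest.approx(fit.params[1] * 1000.0, rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        from marshpace.series import ols_line

        with pytest.raises(ValueError, match="rank-deficient"):
            ols_line(np.zeros(5), np.arange(5.0))

    def test_too_few_points_rejected(self):
        idx = pd.DatetimeIndex(["2020-01-01", "2020-02-01"])
        s = LevelSeries("S1", "monthly", pd.Series([1.0, 2.0], index=idx))
        with pytest.raises(ValueError):
            ols_trend(s)


class TestFitAR1:
    def test_white_noise_phi_near_zero(self):
        rng = np.random.default_rng(0)
        model = fit_ar1(rng.normal(size=1000) * 10)
        assert abs(model.phi) < 0.08

    def test_recovers_phi(self):
        rng = np.random.default_rng(1)
        x = simulate_surrogates(AR1Model(0.6, 8.0), 1000, 1, rng)[0]
        model = fit_ar1(x)
        assert model.phi == pytest.approx(0.6, abs=0.05)

    def test_alternating_sequence_triggers_guard(self):
        # the lag-1 autocorrelation of +a,-a,... sits at the stationarity
        # boundary; the fit must refuse and point at white noise instead
        x = np.tile([5.0, -5.0], 500)
        with pytest.raises(ValueError, match="white-noise"):
            fit_ar1(x)

    def test_gap_tolerant(self):
        rng = np.random.default_rng(2)
        x = simulate_surrogates(AR1Model(0.5, 5.0), 400, 1, rng)[0]
        x[::7] = np.nan
        model = fit_ar1(x)
        assert model.phi == pytest.approx(0.5, abs=0.12)


class TestSurrogates:
    def test_phi_zero_is_white_noise(self):
        s = simulate_surrogates(AR1Model(0.0, 6.0), 500, 200, rng=3)
        assert np.std(s) == pytest.approx(6.0, rel=0.02)

    def test_stationary_marginal_sd(self):
        # sd = innovation / sqrt(1 - phi^2) = 6 / 0.6 = 10
        s = simulate_surrogates(AR1Model(0.8, 6.0), 300, 2000, rng=4)
        assert np.std(s) == pytest.approx(10.0, rel=0.02)

    def test_no_burn_in_bias(self):
        # first column already has the stationary variance
        s = simulate_surrogates(AR1Model(0.9, 4.0), 50, 20000, rng=5)
        expected = 4.0 / np.sqrt(1 - 0.81)
        assert np.std(s[:, 0]) == pytest.approx(expected, rel=0.03)

    def test_deterministic_under_seed(self):
        a = simulate_surrogates(AR1Model(0.5, 3.0), 100, 50, rng=42)
        b = simulate_surrogates(AR1Model(0.5, 3.0), 100, 50, rng=42)
        np.testing.assert_array_equal(a, b)

    def test_white_noise_reduction(self):
        a = white_noise_surrogates(5.0, 80, 40, rng=7)
        b = simulate_surrogates(AR1Model(0.0, 5.0), 80, 40, rng=7)
        np.testing.assert_array_equal(a, b)

    def test_white_noise_lag1_near_zero(self):
        s = white_noise_surrogates(5.0, 100, 10_000, rng=8)
        sc = s - s.mean(axis=1, keepdims=True)
        r1 = np.mean(
            np.einsum("ij,ij->i", sc[:, :-1], sc[:, 1:])
            / np.einsum("ij,ij->i", sc, sc)
        )
        assert abs(r1) < 0.015  # E[r1] ~ -1/n

    def test_zero_sd_all_zero(self):
        assert not white_noise_surrogates(0.0, 10, 5, rng=9).any()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_surrogates(AR1Model(0.2, 1.0), 1, 10, rng=0)


class TestTrendPValue:
    def test_zero_slope_gives_p_one(self):
        ens = ols_trend(monthly_series(np.full(36, 1.0)))
        surr = white_noise_surrogates(5.0, 36, 99, rng=1)
        assert trend_p_value(ens, surr) == pytest.approx(1.0)

    def test_huge_trend_attains_minimum(self):
        ens = ols_trend(monthly_series(np.arange(36.0)))  # ~12 m/yr trend
        surr = white_noise_surrogates(1.0, 36, 99, rng=2)
        assert trend_p_value(ens, surr) == pytest.approx(1 / 100)


class TestTrendEnsemble:
    def test_noise_free_draws_equal_point_rate(self):
        ens = ols_trend(monthly_series(0.001 * np.arange(36.0)))
        out = trend_ensemble(ens, AR1Model(0.0, 0.0), n_draws=500, rng=0)
        np.testing.assert_allclose(out.draws, ens.rate)

    def test_ensemble_mean_near_point_rate(self):
        rng = np.random.default_rng(11)
        s = monthly_series(0.002 * np.arange(156.0) + 0.01 * rng.normal(size=156))
        ens = ols_trend(s)
        model = fit_ar1(ens.residuals * 1000)
        out = trend_ensemble(ens, model, n_draws=5000, rng=12)
        se = out.ensemble_sd / np.sqrt(5000)
        assert abs(out.draws.mean() - ens.rate) < 2 * se

    def test_white_noise_sd_matches_closed_form_slope_se(self):
        # classical OLS slope standard error: sd / sqrt(sum (t - tbar)^2)
        rng = np.random.default_rng(13)
        s = monthly_series(0.01 * rng.normal(size=156))
        ens = ols_trend(s)
        out = trend_ensemble(ens, AR1Model(0.0, 10.0), n_draws=10_000, rng=14)
        t = s.times_decimal()
        se_closed = 10.0 / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert out.ensemble_sd == pytest.approx(se_closed, rel=0.05)

    def test_masking_preserves_sampling_pattern(self):
        vals = 0.001 * np.arange(156.0)
        vals[40:70] = np.nan
        s = monthly_series(vals)
        ens = ols_trend(s)
        assert ens.times.size == 126
        out = trend_ensemble(ens, AR1Model(0.4, 5.0), n_draws=200, rng=15)
        assert out.draws.shape == (200,)


class TestCorrelation:
    def _pair(self, rho_seed):
        rng = np.random.default_rng(rho_seed)
        a = monthly_series(rng.normal(size=60), site_id="A")
        return a

    def test_identical_series_r_one(self):
        a = self._pair(0)
        b = a.with_values(a.values.copy())
        r, p = correlation_p_value(a, b, AR1Model(0.3, 5.0), AR1Model(0.3, 5.0),
                                   n_draws=200, rng=1)
        assert r == pytest.approx(1.0)

    def test_negated_series_r_minus_one_min_p(self):
        a = self._pair(2)
        b = a.with_values(-a.values)
        r, p = correlation_p_value(a, b, AR1Model(0.3, 5.0), AR1Model(0.3, 5.0),
                                   n_draws=200, rng=3)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(1 / 201)

    def test_too_few_common_months_rejected(self):
        a = monthly_series(np.arange(12.0))
        with pytest.raises(ValueError):
            correlation_p_value(a, a, AR1Model(0, 1), AR1Model(0, 1), 10, 0)

    def test_null_calibration(self):
        # independent AR(1) pairs: p < 0.05 should occur ~5% of the time
        rng = np.random.default_rng(4)
        model = AR1Model(0.5, 5.0)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = simulate_surrogates(model, 156, 2, rng)
            a = monthly_series(x[0], site_id="A")
            b = monthly_series(x[1], site_id="B")
            _, p = correlation_p_value(a, b, model, model, n_draws=200, rng=rng)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.04)


class TestPooledRate:
    def test_arithmetic_mean(self):
        ens = [ols_trend(monthly_series(r / 1000.0 * np.arange(25.0) / 12))
               for r in (9.0, 10.0, 11.0, 12.8)]
        assert pooled_point_rate(ens) == pytest.approx(10.7, abs=1e-9)

    def test_single_series(self):
        e = ols_trend(monthly_series(np.arange(25.0)))
        assert pooled_point_rate([e]) == e.rate

    def test_mean_of_rates_equals_rate_of_mean(self):
        rng = np.random.default_rng(5)
        mats = rng.normal(size=(5, 36))
        rates = [ols_trend(monthly_series(m)).rate for m in mats]
        pooled = ols_trend(monthly_series(mats.mean(axis=0))).rate
        assert np.mean(rates) == pytest.approx(pooled, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_point_rate([])
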