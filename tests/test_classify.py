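"""Tide construction, exceedance/flooding probabilities, the seven-way partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from marshpace import (
    CATEGORIES,
    SAFE_CATEGORIES,
    ResponseClassification,
    classify_site,
    cross_site_percentiles,
    deficit_draws,
    flooding_probability,
    p_rate_exceed,
    rate_correlation,
    safe_site_summary,
    tide_triplet,
)
from marshpace.classify import (
    CATCH_UP,
    GIVE_UP_COMPLETE,
    GIVE_UP_IN_PROGRESS,
    GIVE_UP_PROJECTED,
    KEEP_UP_DYNAMIC,
    KEEP_UP_STABLE,
    SPEED_UP,
)
from marshpace.trends import TrendEnsemble

from conftest import monthly_series


def ensemble(draws, site_id="S1"):
    draws = np.asarray(draws, dtype=float)
    return TrendEnsemble(site_id=site_id, rate=float(draws.mean()), intercept=0.0,
                         residual_sd=0.0, n_obs=10, draws=draws)


class TestTideTriplet:
    def test_bracket_arithmetic(self):
        tides = tide_triplet(monthly_series([0.300]), 0.40)
        assert tides["low"].iloc[0] == pytest.approx(0.100)
        assert tides["high"].iloc[0] == pytest.approx(0.500)

    def test_tideless_limit(self):
        tides = tide_triplet(monthly_series([0.2, 0.3]), 0.0)
        assert (tides["low"] == tides["mean"]).all()
        assert (tides["mean"] == tides["high"]).all()

    def test_spread_equals_amplitude_every_month(self):
        rng = np.random.default_rng(0)
        tides = tide_triplet(monthly_series(rng.normal(size=36)), 0.55)
        np.testing.assert_allclose(tides["high"] - tides["low"], 0.55)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            tide_triplet(monthly_series([0.0]), -0.1)


class TestPRateExceed:
    def test_identical_ensembles_tie_to_zero(self):
        # strict ">": a jitter-free tie is not split to 0.5
        e = ensemble(np.full(100, 7.0))
        assert p_rate_exceed(e, ensemble(np.full(100, 7.0))) == 0.0

    def test_same_distribution_near_half(self):
        rng = np.random.default_rng(1)
        a = ensemble(rng.normal(10, 1, 20_000))
        b = ensemble(rng.normal(10, 1, 20_000))
        assert p_rate_exceed(a, b) == pytest.approx(0.5, abs=0.02)

    def test_closed_form_normal_difference(self):
        # cRWL ~ N(10,1), SEC ~ N(5,1): P(diff > 0) = Phi(5 / sqrt(2))
        rng = np.random.default_rng(2)
        a = ensemble(rng.normal(10, 1, 10_000))
        b = ensemble(rng.normal(5, 1, 10_000))
        expected = stats.norm.cdf(5 / np.sqrt(2))
        assert p_rate_exceed(a, b) == pytest.approx(expected, abs=0.005)

    def test_fully_separated_bounds(self):
        a = ensemble(np.linspace(0, 1, 50))
        b = ensemble(np.linspace(5, 6, 50))
        assert p_rate_exceed(a, b) == 0.0
        assert p_rate_exceed(b, a) == 1.0


class TestFloodingProbability:
    def _setup(self, wetland, means, amplitude=0.4):
        idx = pd.date_range("2010-01-01", periods=len(wetland), freq="6MS") + pd.Timedelta(days=14)
        wet = pd.Series(np.asarray(wetland, float), index=idx)
        tide_idx = pd.date_range("2010-01-01", periods=len(means), freq="MS")
        from marshpace import LevelSeries

        mean_tide = LevelSeries(
            "S1", "monthly", pd.Series(np.asarray(means, float), index=tide_idx)
        )
        return wet, tide_triplet(mean_tide, amplitude)

    def test_wetland_above_high_tide_never_floods(self):
        wet, tides = self._setup([1.0] * 4, [0.3] * 19)
        for cond in ("low", "mean", "high"):
            assert flooding_probability(wet, tides, cond) == 0.0

    def test_count_ratio(self):
        wetland = [0.0] * 19 + [9.9]  # below low tide in 19 of 20 occasions
        wet, tides = self._setup(wetland, [0.5] * 115)
        assert flooding_probability(wet, tides, "low") == pytest.approx(0.95)

    def test_monotone_in_tide_condition(self):
        rng = np.random.default_rng(3)
        wet, tides = self._setup(rng.normal(0.3, 0.2, 10), rng.normal(0.3, 0.1, 55))
        p = [flooding_probability(wet, tides, c) for c in ("low", "mean", "high")]
        assert p[0] <= p[1] <= p[2]

    def test_no_overlap_rejected(self):
        wet, tides = self._setup([0.1], [0.3])
        wet.index = wet.index + pd.DateOffset(years=30)
        with pytest.raises(ValueError):
            flooding_probability(wet, tides, "mean")


class TestClassifySite:
    @pytest.mark.parametrize(
        "p_rate,p_flood,expected",
        [
            (0.70, 0.95, GIVE_UP_COMPLETE),
            (0.70, 0.05, GIVE_UP_PROJECTED),
            (0.70, 0.50, GIVE_UP_IN_PROGRESS),
            (0.50, 0.05, KEEP_UP_STABLE),
            (0.50, 0.50, KEEP_UP_DYNAMIC),
            (0.20, 0.60, CATCH_UP),
            (0.20, 0.40, SPEED_UP),
            # boundary conventions
            (0.66, 0.90, GIVE_UP_COMPLETE),
            (0.66, 0.10, GIVE_UP_PROJECTED),
            (0.33, 0.10, KEEP_UP_STABLE),
            (0.33, 0.11, KEEP_UP_DYNAMIC),
            (0.3299, 0.50, SPEED_UP),
            (0.3299, 0.5001, CATCH_UP),
        ],
    )
    def test_rules(self, p_rate, p_flood, expected):
        assert classify_site(p_rate, p_flood) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_total_function_on_unit_square(self, p_rate, p_flood):
        assert classify_site(p_rate, p_flood) in CATEGORIES

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_site(1.2, 0.5)
        with pytest.raises(ValueError):
            classify_site(0.5, -0.1)


class TestDeficits:
    def test_degenerate_ensembles(self):
        d = deficit_draws(ensemble(np.full(10, 15.0)), ensemble(np.full(10, 6.0)))
        np.testing.assert_allclose(d, 9.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = ensemble(rng.normal(size=50)), ensemble(rng.normal(size=50))
        np.testing.assert_allclose(deficit_draws(a, b), -deficit_draws(b, a))

    def test_median_additivity_for_symmetric_ensembles(self):
        rng = np.random.default_rng(5)
        a = ensemble(rng.normal(12, 2, 50_000))
        b = ensemble(rng.normal(5, 1, 50_000))
        d = deficit_draws(a, b)
        assert np.median(d) + np.median(b.draws) == pytest.approx(
            np.median(a.draws), abs=0.05
        )

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(6)
        vals = pd.Series(rng.normal(size=101), index=[f"S{i}" for i in range(101)])
        summary = cross_site_percentiles(vals, probs=(0.25, 0.5))
        ranked = np.sort(vals.to_numpy())
        assert summary.percentiles[0.5] == pytest.approx(ranked[50])
        assert summary.percentiles[0.25] == pytest.approx(
            np.quantile(vals.to_numpy(), 0.25)
        )
        assert summary.percentiles[0.25] <= summary.percentiles[0.5]

    def test_constant_deficits(self):
        vals = pd.Series(np.full(9, 3.3))
        summary = cross_site_percentiles(vals)
        for v in summary.percentiles.values():
            assert v == pytest.approx(3.3)


class TestRateCorrelation:
    def _frame(self, n=200, seed=7, rho=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(15, 5, n)
        y = rho * x + rng.normal(6, 3, n)
        return pd.DataFrame(
            {"crwl_rate": x, "sec_rate": y,
             "organic_fraction": rng.uniform(0, 1, n)}
        )

    def test_trim_count_matches_sort_oracle(self):
        df = self._frame()
        out = rate_correlation(df, rng=0, n_perm=200)
        x = np.sort(df["crwl_rate"].to_numpy())
        lo, hi = np.quantile(x, [0.025, 0.975])
        expected_kept = int(np.sum((x >= lo) & (x <= hi)))
        assert out["n_all"] == expected_kept
        assert out["n_trimmed"] == 200 - expected_kept
        assert 6 <= out["n_trimmed"] <= 14  # ~5% of 200

    def test_collinear_rates(self):
        n = 50
        x = np.linspace(5, 25, n)
        df = pd.DataFrame({"crwl_rate": x, "sec_rate": 0.5 * x + 1.0})
        out = rate_correlation(df, rng=1, n_perm=200)
        assert out["r_all"] == pytest.approx(1.0)

    def test_independent_rates_not_significant(self):
        # mirrors the no-ecogeomorphic-feedback null: independent cRWL and
        # SEC rates should rarely look significant
        hits = 0
        for seed in range(20):
            out = rate_correlation(self._frame(seed=seed), rng=seed, n_perm=400)
            assert abs(out["r_all"]) < 0.25
            hits += out["p_all"] < 0.05
        assert hits <= 3


class TestSafeSummary:
    def _cls(self, category, sid):
        return ResponseClassification(sid, 0.9, 0.9, "low", category)

    def test_all_give_up(self):
        cls_list = [self._cls(GIVE_UP_COMPLETE, f"S{i}") for i in range(5)]
        rates = pd.Series(np.arange(5.0), index=[f"S{i}" for i in range(5)])
        out = safe_site_summary(cls_list, rates, rates)
        assert out["safe_share"] == 0.0

    def test_shares_partition_to_one(self):
        rng = np.random.default_rng(8)
        cats = rng.choice(CATEGORIES, size=40)
        ids = [f"S{i}" for i in range(40)]
        cls_list = [self._cls(c, sid) for c, sid in zip(cats, ids)]
        rates = pd.Series(rng.normal(size=40), index=ids)
        out = safe_site_summary(cls_list, rates, rates)
        assert sum(out["category_shares"].values()) == pytest.approx(1.0)
        assert out["safe_share"] + out["give_up_share"] == pytest.approx(1.0)

    def test_safe_median_rates_reported(self):
        ids = ["A", "B", "C", "D"]
        cats = [GIVE_UP_COMPLETE, GIVE_UP_PROJECTED, CATCH_UP, SPEED_UP]
        cls_list = [self._cls(c, sid) for c, sid in zip(cats, ids)]
        crwl = pd.Series([20.0, 18.0, 9.0, 10.0], index=ids)
        sec = pd.Series([2.0, 3.0, 11.0, 12.0], index=ids)
        out = safe_site_summary(cls_list, crwl, sec)
        assert out["median_crwl_safe"] == pytest.approx(9.5)
        assert out["median_sec_safe"] == pytest.approx(11.5)
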