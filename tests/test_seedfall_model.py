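"""Seedfall regression, mast classification, interval stats, scenarios."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulsepop as pp
from conftest import ramp_temperatures


class TestSeedfallRegression:
    def test_recovers_generating_parameters_exactly(self):
        # dT grid kept non-negative so the back-transform floor never
        # triggers and the regression is an exact inverse of the generator
        dts = np.linspace(0.0, 1.5, 40)
        temps = ramp_temperatures(dts)
        sf = pp.gen_seedfall(temps, a=0.33, b=0.97, residual_sd=0.0, log_offset=1.0)
        reg = pp.fit_seedfall_regression(temps, sf, mode="dT", log_offset=1.0)
        assert reg.intercept == pytest.approx(0.33, abs=1e-8)
        assert reg.slope == pytest.approx(0.97, abs=1e-8)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_seedfall_gives_zero_slope(self):
        temps = ramp_temperatures(np.linspace(-0.5, 0.5, 20))
        years = np.arange(temps.years[0] + 2, temps.years[-1] + 1)
        sf = pp.AnnualSeries(years, np.full(years.size, 7.0))
        reg = pp.fit_seedfall_regression(temps, sf, mode="dT")
        assert reg.slope == 0.0
        assert reg.r_squared == 0.0

    def test_t_mode_uses_previous_summer(self):
        rng = np.random.default_rng(5)
        years = np.arange(1968, 2000)
        temps = pp.AnnualSeries(years, 16.0 + rng.normal(0, 0.5, years.size))
        # generate from the T cue directly: log10(F+1) = a + b*T_{y-1}
        sf_years = years[1:]
        x = temps.values[:-1]
        f = np.power(10.0, -15.0 + 1.0 * x) - 1.0
        sf = pp.AnnualSeries(sf_years, np.maximum(f, 0.0))
        reg = pp.fit_seedfall_regression(temps, sf, mode="T")
        assert reg.slope == pytest.approx(1.0, abs=1e-8)
        assert reg.intercept == pytest.approx(-15.0, abs=1e-6)

    def test_insufficient_overlap_rejected(self):
        temps = ramp_temperatures([0.1, 0.2])
        sf = pp.AnnualSeries(np.array([2010, 2011, 2012]), np.ones(3))
        with pytest.raises(ValueError, match="overlap"):
            pp.fit_seedfall_regression(temps, sf)

    def test_zero_predictor_variance_rejected(self):
        temps = pp.AnnualSeries(np.arange(1968, 1990), np.full(22, 16.0))
        years = np.arange(1970, 1991)
        sf = pp.AnnualSeries(years, np.abs(np.sin(years.astype(float))))
        with pytest.raises(ValueError, match="variance"):
            pp.fit_seedfall_regression(temps, sf, mode="dT")


class TestPredictSeedfall:
    def _reg(self, a, b, offset=0.0):
        return pp.RegressionResult(
            intercept=a, slope=b, r_squared=1.0, p_value=0.0,
            residual_sd=0.0, mode="dT", log_offset=offset, n=25,
        )

    def test_closed_form_at_zero_delta_t(self):
        temps = pp.AnnualSeries(np.arange(1970, 1980), np.full(10, 16.0))
        pred = pp.predict_seedfall(self._reg(0.33, 0.97), temps)
        np.testing.assert_allclose(pred.values, 10**0.33)

    def test_zero_slope_gives_constant_prediction(self):
        rng = np.random.default_rng(2)
        temps = pp.AnnualSeries(np.arange(1970, 1990), 16 + rng.normal(0, 1, 20))
        pred = pp.predict_seedfall(self._reg(0.5, 0.0), temps)
        np.testing.assert_allclose(pred.values, 10**0.5)

    def test_monotone_in_delta_t(self):
        dts = np.linspace(-2, 2, 30)
        temps = ramp_temperatures(dts)
        pred = pp.predict_seedfall(self._reg(0.33, 0.97, offset=1.0), temps)
        assert np.all(np.diff(pred.values[: dts.size]) >= 0)

    def test_predictions_non_negative(self):
        temps = ramp_temperatures(np.linspace(-3, 0, 20))
        pred = pp.predict_seedfall(self._reg(0.33, 0.97, offset=1.0), temps)
        assert np.all(pred.values >= 0)


class TestClassifyMasts:
    def test_single_spike_record(self):
        sf = pp.AnnualSeries(np.arange(2000, 2005), np.array([0, 0, 0, 0, 100.0]))
        rec = pp.classify_masts(sf)
        np.testing.assert_allclose(
            rec.ad, [-0.4472136, -0.4472136, -0.4472136, -0.4472136, 1.78885438],
            atol=1e-7,
        )
        assert rec.ad_thres == pytest.approx(0.4472136, abs=1e-7)
        assert rec.flags.sum() == 1
        assert rec.years[rec.flags][0] == 2004

    def test_symmetric_record_threshold_zero(self):
        sf = pp.AnnualSeries(np.arange(2000, 2003), np.array([1.0, 2.0, 3.0]))
        rec = pp.classify_masts(sf)
        assert rec.ad_thres == 0.0
        # strict inequality: only the year with AD > 0 is a mast
        assert list(rec.flags) == [False, False, True]

    def test_standardized_deviates_have_unit_sample_sd(self):
        rng = np.random.default_rng(7)
        sf = pp.AnnualSeries(np.arange(1968, 2011), rng.lognormal(1, 1.5, 43))
        rec = pp.classify_masts(sf)
        assert np.mean(rec.ad) == pytest.approx(0.0, abs=1e-9)
        assert np.std(rec.ad, ddof=1) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(
        scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
        shift=st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(11)
        base = rng.lognormal(0, 1, 20)
        r1 = pp.classify_masts(pp.AnnualSeries(np.arange(2000, 2020), base))
        r2 = pp.classify_masts(
            pp.AnnualSeries(np.arange(2000, 2020), scale * base + shift)
        )
        np.testing.assert_allclose(r1.ad, r2.ad, atol=1e-8)
        assert list(r1.flags) == list(r2.flags)

    def test_constant_record_rejected(self):
        sf = pp.AnnualSeries(np.arange(2000, 2005), np.full(5, 3.0))
        with pytest.raises(ValueError, match="constant"):
            pp.classify_masts(sf)


class TestClimateThresholds:
    def _mast_record(self, years, flag_years):
        flags = np.isin(years, flag_years)
        return pp.MastRecord(
            years=years, ad=np.zeros(years.size), flags=flags, ad_thres=0.0
        )

    def test_single_mast_year(self):
        temps = ramp_temperatures([1.2, 0.0, 0.0])
        years = temps.years[2:]
        rec = self._mast_record(years, [years[0]])
        t_thres, dt_thres = pp.climate_thresholds(rec, temps)
        assert dt_thres == pytest.approx(1.2)
        assert t_thres == pytest.approx(temps.value_for(years[0] - 1))

    def test_minimum_over_mast_years(self):
        temps = ramp_temperatures([0.8, 1.5, 0.0])
        years = temps.years[2:]
        rec = self._mast_record(years, [years[0], years[1]])
        _, dt_thres = pp.climate_thresholds(rec, temps)
        assert dt_thres == pytest.approx(0.8)

    def test_no_mast_years_rejected(self):
        temps = ramp_temperatures([0.1, 0.1, 0.1])
        rec = self._mast_record(temps.years[2:], [])
        with pytest.raises(ValueError, match="no mast years"):
            pp.climate_thresholds(rec, temps)


def interval_stats_brute(flags):
    """Independent enumeration oracle for mast_interval_stats."""
    n = len(flags)
    singles = sum(1 for f in flags if f)
    doubles = sum(1 for i in range(n - 1) if flags[i] and flags[i + 1])
    idx = [i for i, f in enumerate(flags) if f]
    gaps = [b - a for a, b in zip(idx, idx[1:])]
    mean_gap = sum(gaps) / len(gaps) if gaps else None
    return singles / n, doubles / n, mean_gap


class TestMastIntervalStats:
    def test_hand_example(self):
        s = pp.mast_interval_stats([True, False, False, False, False, True])
        assert s.prop_single == pytest.approx(2 / 6)
        assert s.prop_double == 0.0
        assert s.mean_gap == pytest.approx(5.0)

    def test_all_true(self):
        n = 9
        s = pp.mast_interval_stats([True] * n)
        assert s.prop_single == 1.0
        assert s.prop_double == pytest.approx((n - 1) / n)
        assert s.mean_gap == pytest.approx(1.0)

    def test_fewer_than_two_events_has_undefined_gap(self):
        s = pp.mast_interval_stats([False, True, False])
        assert s.mean_gap is None
        assert s.n_events == 1

    def test_matches_brute_force_on_all_vectors_up_to_length_10(self):
        for n in range(2, 11):
            for flags in itertools.product([False, True], repeat=n):
                s = pp.mast_interval_stats(list(flags))
                ps, pd_, mg = interval_stats_brute(list(flags))
                assert s.prop_single == pytest.approx(ps)
                assert s.prop_double == pytest.approx(pd_)
                if mg is None:
                    assert s.mean_gap is None
                else:
                    assert s.mean_gap == pytest.approx(mg)

    def test_proportions_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            flags = rng.random(20) < 0.3
            s = pp.mast_interval_stats(flags)
            assert 0 <= s.prop_double <= s.prop_single <= 1


class TestAdjustScenario:
    def _ref(self):
        rng = np.random.default_rng(9)
        return pp.AnnualSeries(np.arange(1972, 2011), 16.4 + 0.7 * rng.standard_normal(39))

    def test_identity_when_scenario_equals_reference(self):
        ref = self._ref()
        adj = pp.adjust_scenario(ref, ref)
        np.testing.assert_allclose(adj.values, ref.values, atol=1e-12)

    def test_mean_shift_removed(self):
        ref = self._ref()
        shifted = pp.AnnualSeries(ref.years, ref.values + 2.0)
        adj = pp.adjust_scenario(shifted, ref)
        np.testing.assert_allclose(adj.values, ref.values, atol=1e-9)

    def test_overlap_moments_match_reference(self):
        ref = self._ref()
        rng = np.random.default_rng(10)
        years = np.arange(1972, 2101)
        scen = pp.AnnualSeries(
            years, 15.2 + 0.02 * (years - 1972) + 0.4 * rng.standard_normal(years.size)
        )
        adj = pp.adjust_scenario(scen, ref)
        overlap = np.intersect1d(adj.years, ref.years)
        a = np.array([adj.value_for(y) for y in overlap])
        r = np.array([ref.value_for(y) for y in overlap])
        assert np.mean(a) == pytest.approx(np.mean(r), abs=1e-9)
        assert np.std(a, ddof=1) == pytest.approx(np.std(r, ddof=1), abs=1e-9)

    def test_idempotent(self):
        ref = self._ref()
        rng = np.random.default_rng(12)
        scen = pp.AnnualSeries(
            np.arange(1972, 2050), 15.0 + 0.5 * rng.standard_normal(78)
        )
        once = pp.adjust_scenario(scen, ref)
        twice = pp.adjust_scenario(once, ref)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_zero_variance_rejected(self):
        ref = self._ref()
        scen = pp.AnnualSeries(np.arange(1972, 2011), np.full(39, 15.0))
        with pytest.raises(ValueError, match="variance"):
            pp.adjust_scenario(scen, ref)


class TestDistributionChecks:
    def test_series_vs_itself_has_zero_ks(self):
        rng = np.random.default_rng(1)
        s = pp.AnnualSeries(np.arange(1968, 2011), rng.normal(16, 1, 43))
        rep = pp.distribution_checks(s, comparison=s)
        assert rep["ks_statistic"] == 0.0

    def test_alternating_series_is_strongly_autocorrelated(self):
        vals = np.tile([1.0, -1.0], 25)
        s = pp.AnnualSeries(np.arange(1950, 2000), vals)
        rep = pp.distribution_checks(s)
        # lag-1 autocorrelation ~ -1 => Ljung-Box p ~ 0
        assert rep["ljung_box_p"][0] < 1e-6

    def test_iid_normal_passes_ljung_box_in_most_seeds(self):
        passes = 0
        for seed in range(20):
            t = pp.gen_temperatures(1000, 16.4, 0.7, seed)
            rep = pp.distribution_checks(t)
            passes += rep["ljung_box_p"][0] > 0.05
        assert passes >= 18  # >= 90% of seeds

    def test_short_series_rejected(self):
        s = pp.AnnualSeries(np.arange(2000, 2005), np.ones(5) + np.arange(5))
        with pytest.raises(ValueError, match="short"):
            pp.distribution_checks(s)
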