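"""Pressure-to-rate pipeline: derivatives, smoothing, windows, summaries, growth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanokinetics.gas_model import VesselSpec, extent_from_pressure_drop
from methanokinetics.io_formats import GCResult, ODSeries, PressureSeries
from methanokinetics.kinetics import (
    NoActivePhaseError,
    RateSeries,
    detect_active_window,
    growth_stats,
    k_min,
    mer_from_gc,
    mer_from_pressure,
    resample_series,
    smooth_series,
    summarize_kinetics,
)

R = 8.314


def series_from(times, pressures, vessel=None):
    return PressureSeries("R1", np.asarray(times, float), np.asarray(pressures, float), vessel=vessel)


class TestResample:
    def test_five_minute_grid_to_thirty_minutes(self):
        times = np.arange(0, 10 + 1e-9, 1 / 12)
        s = resample_series(series_from(times, 10 - 0.5 * times), 0.5)
        assert len(s) == 21  # 0, 0.5, ..., 10
        assert np.allclose(np.diff(s.times), 0.5)

    def test_native_spacing_is_identity(self):
        times = np.arange(0, 5.0, 0.5)
        orig = 10 - 0.3 * times
        s = resample_series(series_from(times, orig), 0.5)
        np.testing.assert_allclose(s.pressures, orig, rtol=1e-12)

    def test_linear_trace_interpolates_exactly(self):
        s = resample_series(series_from([0, 1.7, 4.0], [10, 10 - 1.7 * 0.4, 10 - 4.0 * 0.4]), 0.25)
        np.testing.assert_allclose(s.pressures, 10 - 0.4 * s.times, rtol=1e-12)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            resample_series(series_from([0, 1], [10, 9]), 0.0)


class TestMerFromPressure:
    def test_constant_pressure_zero_rate(self, vessel):
        s = series_from(np.arange(0, 5, 0.5), np.full(10, 8.0))
        rates = mer_from_pressure(s, vessel)
        assert np.allclose(rates.mer, 0.0)

    def test_linear_decay_hand_value(self):
        # dp/dt = -1 bar/h, V_gas = 0.1 L, V_liq = 0.06 L, T = 338.15 K.
        # Independent arithmetic: 1 bar/h of headspace is 1e5*1e-4/(R*T) mol/h
        # of gas, /4 for CH4, /0.06 L, *1e3 for mmol.
        vessel = VesselSpec(v_total=0.16, v_liquid=0.06, t_incubation=338.15)
        expected = 1e5 * 0.1e-3 / (R * 338.15) / 4.0 / 0.06 * 1e3
        assert expected == pytest.approx(14.82, abs=0.01)
        times = np.arange(0, 5, 0.5)
        rates = mer_from_pressure(series_from(times, 10 - times), vessel)
        np.testing.assert_allclose(rates.mer, expected, rtol=1e-12)

    def test_stoichiometric_companions(self, vessel):
        times = np.arange(0, 5, 0.5)
        rates = mer_from_pressure(series_from(times, 10 - 0.7 * times), vessel)
        np.testing.assert_allclose(rates.cur, rates.mer, rtol=0, atol=0)
        np.testing.assert_allclose(rates.hur, 4 * rates.mer, rtol=0, atol=0)

    def test_repressurization_jump_rejected(self, vessel):
        s = series_from([0, 0.5, 1.0, 1.5], [10, 9, 2, 10])
        with pytest.raises(ValueError, match="RCB segmentation"):
            mer_from_pressure(s, vessel)

    def test_matches_simulator_rate_pointwise(self, clean_run):
        params, series, _, truth = clean_run
        resampled = resample_series(series, 0.5)
        rates = mer_from_pressure(resampled, params.vessel)
        truth_on_grid = np.interp(rates.times, truth.times, truth.mer_true)
        active = truth_on_grid > 0.2 * truth.mer_max
        inner = slice(2, -2)
        rel = np.abs(rates.mer[inner][active[inner]] - truth_on_grid[inner][active[inner]])
        rel /= truth_on_grid[inner][active[inner]]
        assert rel.max() < 0.05


class TestSmoothing:
    def test_window_one_is_identity(self):
        r = RateSeries(np.arange(5.0), np.array([1.0, 3.0, 2.0, 5.0, 4.0]))
        np.testing.assert_array_equal(smooth_series(r, 1).mer, r.mer)

    def test_constant_series_unchanged(self):
        r = RateSeries(np.arange(9.0), np.full(9, 2.5))
        np.testing.assert_allclose(smooth_series(r, 5).mer, 2.5)

    def test_spike_reduced_to_fifth(self):
        mer = np.zeros(11)
        mer[5] = 7.0
        sm = smooth_series(RateSeries(np.arange(11.0), mer), 5)
        assert sm.mer[5] == pytest.approx(7.0 / 5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_moving_average(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 40))
        values = rng.normal(size=n)
        sm = smooth_series(RateSeries(np.arange(n, dtype=float), values), 5)
        for i in range(n):
            lo, hi = max(0, i - 2), min(n, i + 3)
            assert sm.mer[i] == pytest.approx(values[lo:hi].mean(), rel=1e-12, abs=1e-12)

    def test_window_longer_than_series_rejected(self):
        r = RateSeries(np.arange(3.0), np.zeros(3))
        with pytest.raises(ValueError):
            smooth_series(r, 5)


class TestKMin:
    def test_linear_decay(self):
        times = np.arange(0, 10, 0.5)
        slope, _ = k_min(series_from(times, 10 - 0.5 * times))
        assert slope == pytest.approx(-0.5, rel=1e-12)

    def test_constant_pressure(self):
        slope, t = k_min(series_from(np.arange(0, 5, 0.5), np.full(10, 9.0)))
        assert slope == 0.0 and t == 0.0

    def test_sigmoid_matches_exhaustive_finite_differences(self):
        times = np.arange(0, 30, 0.5)
        p = 2 + 8 / (1 + np.exp((times - 15) / 2.0))
        slope, t_at = k_min(series_from(times, p))
        # oracle: brute-force minimum over all central differences
        best = (np.inf, None)
        for i in range(1, len(times) - 1):
            d = (p[i + 1] - p[i - 1]) / (times[i + 1] - times[i - 1])
            if d < best[0]:
                best = (d, times[i])
        assert slope == pytest.approx(best[0], rel=1e-12)
        assert t_at == best[1] == 15.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            k_min(series_from([0, 1], [10, 9]))


class TestActiveWindow:
    def test_triangular_crossings_analytic(self):
        # MER rises 0 -> 1 over [0, 5], falls back to 0 at t = 10; the line
        # y = t/5 crosses 0.1 at t = 0.5, the descent at t = 9.5.
        times = np.arange(0, 10.5, 0.5)
        mer = np.where(times <= 5, times / 5, 2 - times / 5)
        x_start, x_end = detect_active_window(RateSeries(times, mer), 0.1)
        assert x_start == pytest.approx(0.5)
        assert x_end == pytest.approx(9.5)

    def test_flat_series_raises_no_active_phase(self):
        r = RateSeries(np.arange(0, 5, 0.5), np.full(10, 0.05))
        with pytest.raises(NoActivePhaseError, match="no active phase"):
            detect_active_window(r, 0.1)

    def test_always_above_threshold_returns_full_span(self):
        r = RateSeries(np.arange(0, 5.5, 0.5), np.full(11, 2.0))
        assert detect_active_window(r, 0.1) == (0.0, 5.0)


class TestSummarize:
    def test_constant_rate_global_equals_rate(self, vessel):
        # a linear pressure decay has constant MER, so the window mean is it
        times = np.arange(0, 20 + 1e-9, 1 / 12)
        series = series_from(times, 10 - 0.2 * times)
        res = summarize_kinetics(series, vessel)
        assert res.mer_global == pytest.approx(res.mer_max, rel=1e-9)

    def test_full_conversion_turnover_and_time(self, clean_run):
        params, series, _, truth = clean_run
        res = summarize_kinetics(series, params.vessel)
        assert res.turnover_max == pytest.approx(100.0, abs=0.5)
        assert res.time_to_full_conversion is not None
        assert res.time_to_full_conversion == pytest.approx(
            truth.time_to_full_conversion, abs=0.5
        )

    def test_mer_max_recovered_from_clean_trace(self, clean_run):
        params, series, _, truth = clean_run
        res = summarize_kinetics(series, params.vessel)
        assert abs(res.mer_max - truth.mer_max) / truth.mer_max < 0.05

    def test_k_min_time_marks_mer_peak(self, clean_run):
        params, series, _, _ = clean_run
        res = summarize_kinetics(series, params.vessel)
        assert abs(res.t_k_min - res.t_mer_max) <= 0.5 + 1e-9

    def test_global_rate_bounded_by_peak(self, clean_run):
        params, series, _, _ = clean_run
        res = summarize_kinetics(series, params.vessel)
        assert 0 <= res.mer_global <= res.mer_max

    def test_integral_consistency_with_mole_balance(self, clean_run):
        # trapezoid of MER*V_liq over the run must equal the endpoint
        # pressure-drop mole balance within 1% on a noise-free trace
        params, series, _, _ = clean_run
        resampled = resample_series(series, 0.5)
        rates = mer_from_pressure(resampled, params.vessel)
        integral_mmol = np.trapezoid(rates.mer, rates.times) * params.vessel.v_liquid
        xi_mmol = 1e3 * extent_from_pressure_drop(
            resampled.pressures[0], resampled.pressures[-1],
            params.vessel, params.vessel.t_incubation,
        )
        assert integral_mmol == pytest.approx(xi_mmol, rel=0.01)

    def test_turnover_rate_times_conversion_time_scale(self, clean_run):
        # a full conversion spends ~100% over the active period, so the peak
        # %/h rate times the conversion time has magnitude ~100
        params, series, _, _ = clean_run
        res = summarize_kinetics(series, params.vessel)
        assert res.turnover_rate_max * res.time_to_full_conversion > 100


class TestMerFromGC:
    def test_zero_methane_zero_rate(self, vessel):
        gc = GCResult("R1", 0.0, 40.0)
        assert mer_from_gc(gc, 2.0, vessel, 40.0) == 0.0

    def test_full_conversion_matches_pressure_drop_extent(self, vessel):
        # y_CH4 = 1 at p_end = p0/5: all residual gas is methane, and that
        # amount equals the extent computed from the pressure drop
        gc = GCResult("R1", 1.0, 40.0)
        t = vessel.t_measurement
        rate = mer_from_gc(gc, 2.0, vessel, 40.0, temperature=t)
        xi = extent_from_pressure_drop(10.0, 2.0, vessel, t)
        assert rate * 40.0 * vessel.v_liquid == pytest.approx(1e3 * xi, rel=1e-12)

    def test_halving_duration_doubles_rate(self, vessel):
        gc = GCResult("R1", 0.8, 40.0)
        assert mer_from_gc(gc, 2.0, vessel, 20.0) == pytest.approx(
            2 * mer_from_gc(gc, 2.0, vessel, 40.0), rel=1e-12
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            GCResult("R1", 1.2, 40.0)


class TestGrowthStats:
    def test_two_points_single_interval(self):
        od = ODSeries("R1", [0.0, 10.0], [0.1, 0.8])
        res = growth_stats(od)
        # with one interval mu = mu_average, so the rate collapses to OD_max/OD_1
        assert res.biomass_increase_rate == pytest.approx(0.8 / 0.1)

    def test_doubling_series_hand_value(self):
        # mu_i = ln 2 for both intervals; rate = mean(0.4/0.1, 0.4/0.2) = 3.0
        od = ODSeries("R1", [0.0, 1.0, 2.0], [0.1, 0.2, 0.4])
        res = growth_stats(od)
        assert res.biomass_increase_rate == pytest.approx(3.0)
        assert res.mu_max == pytest.approx(np.log(2))
        assert res.mu_average == pytest.approx(np.log(2))
        assert res.od_max == 0.4

    def test_constant_od_flagged_undefined(self):
        res = growth_stats(ODSeries("R1", [0.0, 1.0, 2.0], [0.3, 0.3, 0.3]))
        assert not res.defined

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            growth_stats(ODSeries("R1", [0.0, 1.0], [0.0, 0.1]))

    def test_mu_average_is_mean_of_intervals(self):
        od = ODSeries("R1", [0.0, 2.0, 3.0, 7.0], [0.05, 0.11, 0.19, 0.52])
        res = growth_stats(od)
        assert res.mu_average == pytest.approx(res.mu_series.mean())
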