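import numpy as np
import pytest
from sklearn.base import clone

import shearwave as sw
from shearwave.errors import NumericalError, SchemaError

from conftest import synthetic_gaussian_traces


class TestSPM:
    def test_impulse_peaks_recovered_exactly(self):
        dt, n_t = 1e-4, 80
        ks = [10, 23, 41, 57]
        values = np.zeros((4, 1, n_t))
        for i, k in enumerate(ks):
            values[i, 0, k] = 1.0
        f = sw.DisplacementField(values, 2e-3 + np.arange(4) * 1e-3,
                                 [25e-3], np.arange(n_t) * dt)
        arr = sw.detect_arrivals_spm(f)
        np.testing.assert_allclose(arr.arrival_times, np.array(ks) * dt)
        assert arr.quality_flags.all()

    def test_gaussian_between_samples_rounds_to_nearest(self, rng):
        dt = 1e-4
        for _ in range(30):
            peaks = 3e-3 + rng.uniform(0, dt, 4) + np.arange(4) * 4 * dt
            f = synthetic_gaussian_traces(peaks, dt=dt)
            arr = sw.detect_arrivals_spm(f)
            # oracle: densely evaluated analytic pulse, argmax rounded to grid
            t_dense = np.linspace(0, f.time_axis[-1], 400_001)
            for i, p in enumerate(peaks):
                y = np.exp(-((t_dense - p) ** 2) / (2 * (0.3e-3) ** 2))
                expected = round(t_dense[np.argmax(y)] / dt) * dt
                assert arr.arrival_times[i] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_channel_flagged_invalid(self):
        f = synthetic_gaussian_traces([3e-3, 4e-3, 5e-3, 6e-3])
        f.values[2, 0, :] = 0.0
        arr = sw.detect_arrivals_spm(f)
        assert not arr.quality_flags[2]
        assert arr.quality_flags[[0, 1, 3]].all()

    def test_all_invalid_is_an_error(self):
        f = synthetic_gaussian_traces([3e-3, 4e-3, 5e-3])
        f.values[:] = 0.0
        with pytest.raises(NumericalError, match="valid peak"):
            sw.detect_arrivals_spm(f)

    def test_window_boundary_peak_flagged(self):
        f = synthetic_gaussian_traces([3e-3, 4e-3, 5e-3, 9e-3])
        arr = sw.detect_arrivals_spm(f, window=(0.0, 6e-3))
        assert not arr.quality_flags[3]  # its peak lies at the window edge


class TestTDPM:
    def test_exact_on_sampled_parabola(self):
        dt, n_t = 1e-4, 30
        t = np.arange(n_t) * dt
        vertex = 3.37 * dt
        values = (1.0 - ((t - vertex) / (10 * dt)) ** 2)[None, None, :]
        values = np.repeat(values, 3, axis=0)
        f = sw.DisplacementField(values, 2e-3 + np.arange(3) * 1e-3, [25e-3], t)
        arr = sw.detect_arrivals_tdpm(f, upsample_factor=8)
        np.testing.assert_allclose(arr.arrival_times, vertex, atol=1e-9)

    def test_never_worse_than_spm_on_analytic_gaussian(self, rng):
        dt = 1e-4
        for _ in range(100):
            peaks = 3e-3 + rng.uniform(0, dt, 3) + np.arange(3) * 5 * dt
            f = synthetic_gaussian_traces(peaks, dt=dt)
            spm = sw.detect_arrivals_spm(f).arrival_times
            tdpm = sw.detect_arrivals_tdpm(f).arrival_times
            assert np.all(np.abs(tdpm - peaks) <= np.abs(spm - peaks) + 1e-9)

    def test_refined_time_stays_within_one_sample(self, rng):
        f = synthetic_gaussian_traces(3e-3 + np.arange(4) * 6e-4)
        spm = sw.detect_arrivals_spm(f).arrival_times
        tdpm = sw.detect_arrivals_tdpm(f).arrival_times
        assert np.all(np.abs(tdpm - spm) <= f.dt + 1e-15)

    def test_reduces_to_spm_when_refinement_disabled(self):
        f = synthetic_gaussian_traces([3.1e-3, 4.23e-3, 5.7e-3, 6.4e-3])
        a = sw.detect_arrivals_tdpm(f, upsample_factor=1, refine=False)
        b = sw.detect_arrivals_spm(f)
        np.testing.assert_array_equal(a.arrival_times, b.arrival_times)

    def test_invalid_upsample_factor(self):
        f = synthetic_gaussian_traces([3e-3, 4e-3, 5e-3])
        with pytest.raises(SchemaError):
            sw.detect_arrivals_tdpm(f, upsample_factor=0)


class TestSpeedRegression:
    def test_perfect_line(self):
        x = 2e-3 + np.arange(8) * 1e-3
        arr = sw.ArrivalTimes(x, x / 2.0, np.ones(8), np.ones(8, bool))
        est = sw.fit_speed_regression(arr)
        assert est.speed == pytest.approx(2.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = 2e-3 + np.arange(8) * 1e-3
        t = x / 3.0 + rng.normal(0, 0.05e-3, 8)
        arr = sw.ArrivalTimes(x, t, np.ones(8), np.ones(8, bool))
        est = sw.fit_speed_regression(arr)
        # independent closed-form least squares via the normal equations
        A = np.column_stack([np.ones(8), t])
        coef = np.linalg.solve(A.T @ A, A.T @ x)
        assert est.speed == pytest.approx(coef[1], abs=1e-12)

    def test_equal_arrival_times_error(self):
        x = np.arange(4) * 1e-3
        arr = sw.ArrivalTimes(x, np.full(4, 3e-3), np.ones(4), np.ones(4, bool))
        with pytest.raises(NumericalError, match="infinite"):
            sw.fit_speed_regression(arr)

    def test_too_few_valid_channels_error(self):
        x = np.arange(4) * 1e-3
        flags = np.array([True, True, False, False])
        arr = sw.ArrivalTimes(x, x / 2, np.ones(4), flags)
        with pytest.raises(NumericalError, match="at least 3"):
            sw.fit_speed_regression(arr)

    def test_negative_slope_error(self):
        x = np.arange(5) * 1e-3
        arr = sw.ArrivalTimes(x, x[::-1] / 2.0, np.ones(5), np.ones(5, bool))
        with pytest.raises(NumericalError, match="non-physical"):
            sw.fit_speed_regression(arr)

    def test_robust_pass_discards_gross_outlier(self):
        x = 2e-3 + np.arange(20) * 1e-3
        t = x / 2.0
        t = t.copy()
        t[8] += 2e-3
        arr = sw.ArrivalTimes(x, t, np.ones(20), np.ones(20, bool))
        plain = sw.fit_speed_regression(arr)
        robust = sw.fit_speed_regression(arr, robust=True)
        assert abs(robust.speed - 2.0) < abs(plain.speed - 2.0)
        assert robust.n_channels_used == 19
        assert robust.speed == pytest.approx(2.0, abs=1e-12)


class TestTSPM:
    def test_integer_shift_copies_exact(self):
        dt, n_t = 1e-4, 100
        t = np.arange(n_t) * dt
        pulse = np.exp(-((t - 3e-3) ** 2) / (2 * (0.3e-3) ** 2))
        # pitch 0.5 mm at 2 m/s -> shift 0.25 ms = 2.5 samples; use 1 mm pitch
        values = np.stack([np.roll(pulse, 5 * i) for i in range(5)])[:, None, :]
        f = sw.DisplacementField(values, 2e-3 + np.arange(5) * 1e-3, [25e-3], t)
        est = sw.estimate_tspm(f)
        assert est.speed == pytest.approx(2.0, abs=1e-12)
        assert est.method == "TSPM"

    def test_non_integer_shifts_within_1pc_and_lags_match_dense_oracle(self, rng):
        dt = 1e-4
        c = 2.2
        pitch = 0.5e-3
        peaks = 2e-3 + np.arange(6) * pitch / c
        f = synthetic_gaussian_traces(peaks, dt=dt, pitch=pitch)
        model = sw.TSPMEstimator()
        est = model.estimate(f)
        assert est.speed == pytest.approx(c, rel=0.01)
        # dense-grid cross-correlation oracle: spline-resample both traces
        # 50x, correlate discretely, take the argmax lag
        from scipy.interpolate import CubicSpline

        lags_impl = np.diff(model.cumulative_lags_)
        t = f.time_axis
        up = 50
        tf = np.arange((t.size - 1) * up + 1) * dt / up
        for i, got in enumerate(lags_impl):
            y1 = CubicSpline(t, f.values[i, 0])(tf)
            y2 = CubicSpline(t, f.values[i + 1, 0])(tf)
            corr = np.correlate(y2, y1, mode="full")
            oracle = (int(np.argmax(corr)) - (tf.size - 1)) * dt / up
            assert abs(got - oracle) <= dt / 10

    def test_two_channels_insufficient(self):
        f = synthetic_gaussian_traces([3e-3, 4e-3])
        with pytest.raises((NumericalError, SchemaError)):
            sw.estimate_tspm(f)

    def test_boundary_peak_drops_pair(self):
        f = synthetic_gaussian_traces([2e-3, 2.5e-3, 3e-3, 9e-3])
        # last inter-channel delay (6 ms) exceeds max_lag -> pair dropped
        est = sw.TSPMEstimator(max_lag_s=1e-3).estimate(f)
        assert est.n_channels_used == 3


class TestRadon:
    def test_exact_linear_moveout_in_grid(self, clean_field_2ms):
        est = sw.estimate_radon(clean_field_2ms, speed_range=(1.0, 4.0))
        # geomspace(1, 4, 201) contains exactly 2.0 at its midpoint
        assert est.speed == pytest.approx(2.0, abs=1e-12)
        assert est.method == "RADON"

    def test_matches_exhaustive_grid_oracle(self, rng):
        for trial in range(10):
            c = float(rng.uniform(1.5, 3.0))
            peaks = 1.5e-3 + np.arange(5) * 0.5e-3 / c
            f = synthetic_gaussian_traces(peaks, n_t=60)
            f = sw.DisplacementField(f.values + 0.05 * rng.normal(size=f.values.shape),
                                     f.lateral_axis, f.depth_axis, f.time_axis)
            model = sw.RadonSumEstimator(speed_range=(1.0, 5.0), n_speeds=41)
            est = model.estimate(f)
            # independent brute force over every (speed, intercept) pair
            speeds = model.candidate_speeds()
            t = f.time_axis
            dx = f.lateral_axis - f.lateral_axis[0]
            best = (-np.inf, None, None)
            for cc in speeds:
                for t0 in t:
                    s = 0.0
                    for ch in range(5):
                        s += np.interp(t0 + dx[ch] / cc, t, np.abs(f.values[ch, 0]),
                                       left=0, right=0)
                    if s > best[0]:
                        best = (s, cc, t0)
            assert est.speed == pytest.approx(best[1], abs=1e-12)
            assert est.intercept == pytest.approx(best[2], abs=1e-12)

    def test_out_of_range_true_speed_raises_boundary_error(self, clean_field_2ms):
        with pytest.raises(NumericalError, match="widen speed_range"):
            sw.estimate_radon(clean_field_2ms, speed_range=(3.0, 5.0))


class TestSklearnCompat:
    @pytest.mark.parametrize("cls,kw", [
        (sw.SPMEstimator, {}),
        (sw.TDPMEstimator, {"upsample_factor": 4}),
        (sw.TSPMEstimator, {}),
        (sw.RadonSumEstimator, {"speed_range": (1.0, 4.0)}),
    ])
    def test_params_roundtrip_and_fit_attributes(self, cls, kw, clean_field_2ms):
        model = cls(**kw)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        cloned.set_params(depth_index=0)
        cloned.fit(clean_field_2ms)
        assert cloned.speed_ == pytest.approx(2.0, rel=0.05)
        assert 0.0 <= cloned.r_squared_ <= 1.0
        assert cloned.n_channels_used_ >= 3

    def test_noiseless_fits_have_unit_r_squared(self, clean_field_2ms):
        assert sw.TDPMEstimator().fit(clean_field_2ms).r_squared_ == pytest.approx(1.0, abs=1e-9)
        assert sw.TSPMEstimator().fit(clean_field_2ms).r_squared_ == pytest.approx(1.0, abs=1e-9)
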