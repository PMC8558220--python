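"""Beat windows, activation-time measurement, isochrones, origin calls,
and conduction-velocity estimation."""

import warnings

import numpy as np
import pytest

from pacemap import activation
from pacemap.activation import ActivationMap, BeatWindow
from pacemap.extract import Mask
from pacemap.simulate import ap_template


def planar_stack(n_cols=40, n_rows=40, slope_ms_per_px=0.1, frame_rate=500.0,
                 duration_s=0.5):
    """Planar wave along columns: activation at col · slope."""
    t_act = np.arange(n_cols)[None, :] * slope_ms_per_px * np.ones((n_rows, 1))
    t_ms = np.arange(int(frame_rate * duration_s)) / frame_rate * 1000.0
    return ap_template(t_ms[:, None, None] - t_act[None], 20.0, 150.0), t_act


class TestTraces:
    def test_mean_trace_of_uniform_stack(self):
        stack = np.full((10, 4, 4), 0.7)
        tr = activation.spatial_mean_trace(stack, Mask(np.ones((4, 4), bool)))
        assert np.allclose(tr, 0.7)

    def test_mean_trace_half_and_half(self):
        stack = np.zeros((5, 4, 4))
        stack[:, :, 2:] = 1.0
        tr = activation.spatial_mean_trace(stack, Mask(np.ones((4, 4), bool)))
        assert np.allclose(tr, 0.5)

    def test_upstroke_rate_of_linear_ramp(self):
        """Slope 0.1/frame at 52 Hz equals 0.1·52/1000 per ms."""
        tr = np.arange(100) * 0.1
        d = activation.upstroke_rate(tr, 52.0)
        assert np.allclose(d, 0.1 * 52.0 / 1000.0)

    def test_upstroke_rate_of_constant_is_zero(self):
        assert np.allclose(activation.upstroke_rate(np.ones(50), 52.0), 0.0)

    def test_sine_peak_derivative_matches_calculus(self):
        """Max d/dt of A·sin(ωt) is A·ω, recovered within 2%."""
        fr = 1000.0
        t = np.arange(5000) / fr  # s
        f = 2.0  # Hz
        tr = np.sin(2 * np.pi * f * t)
        d = activation.upstroke_rate(tr, fr)  # per ms
        expected = 2 * np.pi * f / 1000.0
        assert d.max() == pytest.approx(expected, rel=0.02)


class TestBeatDetection:
    def test_counts_clean_pacing(self):
        from pacemap.simulate import simulate_voltage_trace
        tr = simulate_voltage_trace(500.0, 5.0, 52.0, snr=0.0, seed=0)
        windows = activation.detect_beats(tr, 52.0)
        assert len(windows) == 10

    def test_flat_trace_yields_no_beats(self):
        assert activation.detect_beats(np.ones(500), 52.0) == []

    def test_pacing_at_refractory_boundary_kept(self):
        from pacemap.simulate import simulate_voltage_trace
        tr = simulate_voltage_trace(300.0, 6.0, 52.0, snr=0.0, seed=0)
        windows = activation.detect_beats(tr, 52.0, min_interval_ms=290.0)
        assert len(windows) == 20

    def test_windows_ordered_and_disjoint(self):
        from pacemap.simulate import simulate_voltage_trace
        tr = simulate_voltage_trace(400.0, 5.0, 52.0, snr=20.0, seed=1)
        windows = activation.detect_beats(tr, 52.0)
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.end_frame <= b.start_frame


class TestActivationTime:
    def test_recovers_known_activation(self):
        fr = 52.0
        t_ms = np.arange(int(20 * fr)) / fr * 1000.0
        t0 = 1000.0
        tr = ap_template(t_ms - t0, 20.0, 150.0)
        w = BeatWindow(0, int((t0 - 150) * fr / 1000), int((t0 + 250) * fr / 1000),
                       t0)
        coarse = activation.activation_time(tr, w, fr, refine=False)
        fine = activation.activation_time(tr, w, fr, refine=True)
        target = t0 + 10.0  # template max-slope point
        assert abs(coarse - target) <= 0.5 * 1000.0 / fr
        assert abs(fine - target) <= 2.0

    def test_flat_pixel_returns_nan(self):
        w = BeatWindow(0, 10, 40, 0.0)
        assert np.isnan(activation.activation_time(np.full(100, np.nan), w, 52.0))

    def test_tie_broken_to_earlier_frame(self):
        tr = np.zeros(60)
        tr[20] = 1.0
        tr[40] = 1.0  # two identical upstrokes
        w = BeatWindow(0, 0, 60, 0.0)
        t = activation.activation_time(tr, w, 52.0, refine=False)
        assert t == pytest.approx(19 / 52.0 * 1000.0)  # gradient peaks at 19


class TestActivationMaps:
    def test_planar_wave_linear_map(self):
        """v = 100 µm/ms on 10 µm pixels → 0.1 ms/pixel, R² > 0.99."""
        stack, t_act = planar_stack()
        mask = Mask(np.ones((40, 40), bool))
        tr = activation.spatial_mean_trace(stack, mask)
        windows = activation.detect_beats(tr, 500.0, min_interval_ms=100.0)
        amap = activation.build_activation_map(stack, mask, windows,
                                               frame_rate=500.0)[0]
        rs, cs = np.nonzero(np.isfinite(amap.times))
        coef = np.polyfit(cs, amap.times[rs, cs], 1)
        assert coef[0] == pytest.approx(0.1, rel=0.05)
        pred = np.polyval(coef, cs)
        resid = amap.times[rs, cs] - pred
        r2 = 1 - resid.var() / amap.times[rs, cs].var()
        assert r2 > 0.99

    def test_single_pixel_mask_map_is_zero(self):
        stack, _ = planar_stack(n_cols=8, n_rows=8)
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        m = Mask(mask)
        tr = activation.spatial_mean_trace(stack, m)
        windows = activation.detect_beats(tr, 500.0, min_interval_ms=100.0)
        amap = activation.build_activation_map(stack, m, windows,
                                               frame_rate=500.0)[0]
        assert np.nansum(np.abs(amap.times)) == 0.0

    def test_map_minimum_is_exactly_zero(self, small_run, full_mask):
        from pacemap import pipeline
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pipeline.simulate_and_measure_rate(
                small_run["config"], seed=11, mask=full_mask,
                min_interval_ms=200.0)
            maps = activation.build_activation_map(res["stack"], res["mask"],
                                                   res["windows"])
        for m in maps:
            if np.isfinite(m.times).any():
                assert np.nanmin(m.times) == 0.0
                assert np.nanmin(m.times[np.isfinite(m.times)]) >= 0.0

    def test_relative_times_invariant_to_monotone_rescale(self):
        stack, _ = planar_stack(n_cols=16, n_rows=16)
        mask = Mask(np.ones((16, 16), bool))
        tr = activation.spatial_mean_trace(stack, mask)
        windows = activation.detect_beats(tr, 500.0, min_interval_ms=100.0)
        a = activation.build_activation_map(stack, mask, windows,
                                            frame_rate=500.0)[0]
        b = activation.build_activation_map(2.0 * stack + 5.0, mask, windows,
                                            frame_rate=500.0)[0]
        np.testing.assert_allclose(a.times, b.times, equal_nan=True)


class TestIsochrones:
    def _linear_map(self, tmax=10.0):
        times = np.linspace(0.0, tmax, 11)[None, :] * np.ones((5, 1))
        return ActivationMap(0, times, np.ones_like(times))

    def test_level_count_for_linear_map(self):
        levels, bands = activation.isochrone_levels(self._linear_map(), 2.0)
        assert len(levels) == 6
        assert bands.min() == 0

    def test_step_exceeding_range_gives_single_band(self):
        _, bands = activation.isochrone_levels(self._linear_map(), 50.0)
        assert set(bands.ravel()) == {0}

    def test_planar_band_areas_equal(self):
        stack, _ = planar_stack()
        mask = Mask(np.ones((40, 40), bool))
        tr = activation.spatial_mean_trace(stack, mask)
        windows = activation.detect_beats(tr, 500.0, min_interval_ms=100.0)
        amap = activation.build_activation_map(stack, mask, windows,
                                               frame_rate=500.0)[0]
        _, bands = activation.isochrone_levels(amap, 1.0)
        areas = np.bincount(bands[bands >= 0].ravel())
        # planar wave: interior bands cover equal areas (±1 pixel column)
        interior = areas[1:-1]
        assert interior.std() / interior.mean() < 0.2

    def test_all_nan_map_errors(self):
        amap = ActivationMap(0, np.full((4, 4), np.nan), np.full((4, 4), np.nan))
        with pytest.raises(ValueError):
            activation.isochrone_levels(amap, 2.0)


class TestOrigins:
    def _radial_map(self, origin, shape=(32, 32)):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        times = np.hypot(rr - origin[0], cc - origin[1]) * 1.0
        return ActivationMap(0, times, np.ones_like(times))

    def test_single_focus_recovered(self):
        call = activation.find_origins(self._radial_map((2, 16)))
        assert len(call.sites) == 1
        r, c, t, _ = call.sites[0]
        assert np.hypot(r - 2, c - 16) <= 2
        assert call.classification == ["primary"]

    def test_two_opposite_foci_both_reported(self):
        a = self._radial_map((2, 16)).times
        b = self._radial_map((29, 16)).times
        times = np.minimum(a, b)
        call = activation.find_origins(
            ActivationMap(0, times, np.ones_like(times)), early_quantile=0.1)
        assert len(call.sites) == 2
        found = {tuple(np.round(s[:2]).astype(int)) for s in call.sites}
        assert all(min(np.hypot(r - 2, c - 16), np.hypot(r - 29, c - 16)) <= 2
                   for r, c in found)

    def test_uniform_activation_degenerates_to_one_cluster(self):
        times = np.zeros((16, 16))
        call = activation.find_origins(
            ActivationMap(0, times, np.ones_like(times)))
        assert len(call.sites) == 1
        assert call.sites[0][3] == 256  # cluster spans the whole mask


class TestConductionVelocity:
    def test_planar_wave_speed_recovered(self):
        stack, _ = planar_stack()  # 0.1 ms/px on 10 µm pixels = 100 µm/ms
        mask = Mask(np.ones((40, 40), bool))
        tr = activation.spatial_mean_trace(stack, mask)
        windows = activation.detect_beats(tr, 500.0, min_interval_ms=100.0)
        amap = activation.build_activation_map(stack, mask, windows,
                                               frame_rate=500.0)[0]
        cv = activation.estimate_conduction_velocity(amap, 10.0)
        assert cv == pytest.approx(100.0, rel=0.05)

    def test_noisy_planar_wave_within_15_percent(self):
        """Default velocity (10 µm/ms) at the 52 Hz acquisition rate,
        additive noise at SNR 10."""
        fr = 52.0
        t_act = 100.0 + np.arange(40)[None, :] * 1.0 * np.ones((40, 1))
        t_ms = np.arange(int(fr * 0.8)) / fr * 1000.0
        stack = ap_template(t_ms[:, None, None] - t_act[None], 20.0, 150.0)
        rng = np.random.default_rng(0)
        stack = stack + rng.normal(0, 0.1, stack.shape)  # SNR 10
        mask = Mask(np.ones((40, 40), bool))
        tr = activation.spatial_mean_trace(stack, mask)
        windows = activation.detect_beats(tr, fr, min_interval_ms=100.0)
        amap = activation.build_activation_map(stack, mask, windows,
                                               frame_rate=fr)[0]
        cv = activation.estimate_conduction_velocity(amap, 10.0)
        assert cv == pytest.approx(10.0, rel=0.15)

    def test_simultaneous_activation_flagged(self):
        times = np.zeros((10, 10))
        amap = ActivationMap(0, times, np.ones_like(times))
        assert np.isnan(activation.estimate_conduction_velocity(amap, 10.0))

    def test_too_few_pixels_rejected(self):
        times = np.full((10, 10), np.nan)
        times[0, :5] = np.arange(5.0)
        with pytest.raises(ValueError, match="20"):
            activation.estimate_conduction_velocity(
                ActivationMap(0, times, np.ones_like(times)), 10.0)
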