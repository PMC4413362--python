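"""End-tidal detection, hold interpolation, HRF convolution, frame resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvrbh import (
    CapnoTrace,
    EndTidalSeries,
    HrfSpec,
    Paradigm,
    UniformSeries,
    convolve_hrf,
    detect_end_tidal,
    interpolate_breath_hold,
    resample_to_frames,
)
from cvrbh.errors import (
    CoverageError,
    NoBreathsError,
    ResolutionError,
    UnboundedHoldError,
)


def sinusoid_trace(freq=0.25, lo=38.0, hi=42.0, duration=60.0, fs=50.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    mid, amp = (hi + lo) / 2, (hi - lo) / 2
    return CapnoTrace(t, mid + amp * np.sin(2 * np.pi * freq * t), fs)


class TestDetectEndTidal:
    def test_sinusoid_maxima_match_local_max_scan(self):
        """Every sinusoid crest is one breath; values sit at the 42 mmHg maxima."""
        trace = sinusoid_trace()
        ets = detect_end_tidal(trace)
        # oracle: exhaustive interior local-maximum scan with the known period
        y = trace.pco2
        interior = np.nonzero((y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
        crest_times = []
        for i in interior:
            if abs(y[i] - 42.0) < 0.01:
                if not crest_times or trace.time[i] - crest_times[-1] > 2.0:
                    crest_times.append(trace.time[i])
        assert ets.petco2.size == len(crest_times)
        assert np.allclose(ets.petco2, 42.0, atol=0.05)
        assert np.allclose(ets.breath_end_time, crest_times, atol=0.3)

    def test_single_breath_single_value_at_global_max(self):
        fs = 50.0
        t = np.arange(0.0, 10.0, 1.0 / fs)
        y = 5.0 + 35.0 * np.exp(-((t - 5.0) ** 2) / 2.0)
        ets = detect_end_tidal(CapnoTrace(t, y, fs))
        assert ets.petco2.size == 1
        assert ets.petco2[0] == pytest.approx(y.max())
        assert ets.breath_end_time[0] == pytest.approx(5.0, abs=0.1)

    def test_constant_trace_raises(self):
        t = np.arange(0.0, 30.0, 0.02)
        with pytest.raises(NoBreathsError):
            detect_end_tidal(CapnoTrace(t, np.full(t.size, 40.0), 50.0))

    def test_trace_shorter_than_paradigm_raises(self):
        with pytest.raises(CoverageError):
            detect_end_tidal(sinusoid_trace(duration=60.0), Paradigm())

    def test_close_breaths_are_merged(self):
        """Two crests 1 s apart fall under the minimum inter-breath interval."""
        fs = 100.0
        t = np.arange(0.0, 20.0, 1.0 / fs)
        y = 30.0 + 8 * np.exp(-((t - 8.0) ** 2) / 0.18) \
            + 8 * np.exp(-((t - 9.0) ** 2) / 0.18)
        ets = detect_end_tidal(CapnoTrace(t, y, fs))
        assert ets.petco2.size == 1


class TestInterpolateBreathHold:
    def test_linear_ramp_across_hold(self):
        ets = EndTidalSeries([0.0, 15.0], [40.0, 48.0], [(0.0, 15.0)])
        series = interpolate_breath_hold(ets, dt=0.1)
        assert series.values[75] == pytest.approx(44.0)  # midpoint t=7.5 s

    def test_equal_bounds_give_constant_hold(self):
        ets = EndTidalSeries([0.0, 15.0], [40.0, 40.0], [(0.0, 15.0)])
        series = interpolate_breath_hold(ets, dt=0.1)
        assert np.allclose(series.values, 40.0)

    def test_between_breath_interpolation_is_linear(self):
        ets = EndTidalSeries([0.0, 4.0, 8.0], [38.0, 40.0, 42.0], [])
        series = interpolate_breath_hold(ets, dt=0.1)
        assert series.values[20] == pytest.approx(39.0)  # midpoint breaths 1-2
        # continuous, piecewise linear, max equals max input end-tidal value
        assert series.values.max() == pytest.approx(42.0)
        assert np.all(np.abs(np.diff(series.values, 2)) < 1e-9)

    def test_unbounded_hold_raises(self):
        ets = EndTidalSeries([0.0, 5.0], [40.0, 41.0], [(10.0, 25.0)])
        with pytest.raises(UnboundedHoldError):
            interpolate_breath_hold(ets)

    def test_detections_inside_hold_are_discarded(self):
        ets = EndTidalSeries([0.0, 7.5, 15.0], [40.0, 20.0, 48.0], [(0.0, 15.0)])
        series = interpolate_breath_hold(ets, dt=0.1)
        assert series.values[75] == pytest.approx(44.0)


class TestConvolveHrf:
    def test_constant_input_preserved(self):
        series = UniformSeries(np.full(400, 40.0), dt=0.1)
        out = convolve_hrf(series)
        assert np.allclose(out.values, 40.0, atol=1e-9)

    def test_step_converges_to_step_height(self):
        """Unit-area kernel conserves a sustained step once support has passed."""
        hrf = HrfSpec()
        x = np.concatenate([np.full(100, 40.0), np.full(700, 48.0)])
        out = convolve_hrf(UniformSeries(x, dt=0.1), hrf)
        support = int(hrf.duration / hrf.dt)
        assert np.allclose(out.values[100 + support:], 48.0, atol=1e-6)

    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, k, seed):
        r = np.random.default_rng(seed)
        x = 40 + 5 * r.standard_normal(300)
        a = convolve_hrf(UniformSeries(k * x, dt=0.1)).values
        b = k * convolve_hrf(UniformSeries(x, dt=0.1)).values
        assert np.allclose(a, b, rtol=1e-12, atol=1e-9)

    def test_linearity(self):
        r = np.random.default_rng(1)
        x = 40 + 3 * r.standard_normal(300)
        two = convolve_hrf(UniformSeries(2 * x, dt=0.1)).values
        one = convolve_hrf(UniformSeries(x, dt=0.1)).values
        assert np.allclose(two, 2 * one)

    def test_step_response_matches_kernel_integral_oracle(self):
        """Step response equals the cumulative integral of the normalized kernel."""
        hrf = HrfSpec(dt=0.01)
        onset = 2000
        x = np.concatenate([np.zeros(onset), np.ones(8000)])
        out = convolve_hrf(UniformSeries(x, dt=hrf.dt), hrf)
        # oracle: trapezoid integration of the unnormalized double-gamma
        from scipy.stats import gamma as gd

        t = np.arange(0.0, hrf.duration, hrf.dt)
        raw = gd.pdf(t, 6.0, scale=1.0) - gd.pdf(t, 16.0, scale=1.0) / 6.0
        area = np.trapezoid(raw, t)
        at = int(hrf.peak_delay / hrf.dt)
        expected = np.trapezoid(raw[: at + 1], t[: at + 1]) / area
        assert out.values[onset + at] == pytest.approx(expected, abs=5e-3)

    def test_dt_mismatch_raises(self):
        with pytest.raises(ResolutionError):
            convolve_hrf(UniformSeries(np.zeros(100), dt=0.2), HrfSpec(dt=0.1))


class TestResampleToFrames:
    def test_zero_delay_on_frame_grid_is_identity(self):
        tr = 2.0
        vals = np.arange(10, dtype=float)
        series = UniformSeries(vals, dt=tr, t0=0.5 * tr)  # frame midpoints
        reg = resample_to_frames(series, tr=tr, n_frames=10, delay=0.0)
        assert np.allclose(reg.values, vals)

    def test_tr_delay_shifts_ramp_one_frame(self):
        tr = 2.0
        series = UniformSeries(np.arange(40, dtype=float) * 0.1, dt=0.1)
        a = resample_to_frames(series, tr, 3, delay=0.0).values
        b = resample_to_frames(series, tr, 3, delay=tr).values
        assert np.allclose(b[1:], a[:-1])

    def test_analytic_sinusoid_delay(self):
        tr, delay = 2.0, 3.4
        t = np.arange(0.0, 100.0, 0.1)
        series = UniformSeries(np.sin(2 * np.pi * t / 40.0), dt=0.1)
        reg = resample_to_frames(series, tr, 20, delay=delay, t0=10.0)
        ft = 10.0 + (np.arange(20) + 0.5) * tr
        assert np.allclose(reg.values, np.sin(2 * np.pi * (ft - delay) / 40.0),
                           atol=1e-4)

    def test_nonpositive_frames_raises(self):
        with pytest.raises(ValueError):
            resample_to_frames(UniformSeries(np.zeros(10), dt=0.1), 2.0, 0)
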