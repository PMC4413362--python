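"""End-tidal CO2 regressor construction from a raw capnograph trace.

The chain implemented here turns the 200 Hz pressure recording from a nasal
cannula into a quantitative BOLD model in mmHg:

1. :func:`detect_end_tidal` — find the expiratory maximum of every breath
   (the end-tidal partial pressure, PETCO2).
2. :func:`interpolate_breath_hold` — bridge each apnea linearly between the
   last pre-hold breath and the post-hold "quick exhalation" value, and put
   the per-breath values on a uniform 0.1 s grid.
3. :func:`convolve_hrf` — scale-invariant convolution with the canonical
   double-gamma hemodynamic response function, so a sustained rise of
   A mmHg still reads A mmHg after convolution.
4. :func:`resample_to_frames` — shift by a candidate hemodynamic delay and
   sample at the BOLD frame midpoints.

Because the convolution kernel has unit area, the regressor amplitude keeps
the physical units of the CO2 excursion, which is what makes the fitted GLM
slope a quantitative CVR measure in %BOLD per mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gamma as gamma_dist

from .errors import (
    CoverageError,
    NoBreathsError,
    ResolutionError,
    UnboundedHoldError,
)
from .paradigm import Paradigm

__all__ = [
    "CapnoTrace",
    "EndTidalSeries",
    "HrfSpec",
    "Co2Regressor",
    "UniformSeries",
    "RegressorBuilder",
    "detect_end_tidal",
    "interpolate_breath_hold",
    "convolve_hrf",
    "resample_to_frames",
    "build_regressor_series",
]


@dataclass
class CapnoTrace:
    """Raw capnograph recording: time (s), pCO2 (mmHg), sampling rate (Hz)."""

    time: np.ndarray
    pco2: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if self.time.size != self.pco2.size or self.time.size < 2:
            raise ValueError("time and pco2 must have equal length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.pco2)) or np.any(self.pco2 < 0):
            raise ValueError("pco2 must be finite and non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class EndTidalSeries:
    """Per-breath end-tidal pCO2 values anchored at breath-end times."""

    breath_end_time: np.ndarray
    petco2: np.ndarray
    hold_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.breath_end_time = np.asarray(self.breath_end_time, dtype=float)
        self.petco2 = np.asarray(self.petco2, dtype=float)
        if self.breath_end_time.size != self.petco2.size:
            raise ValueError("breath_end_time and petco2 must have equal length")
        if np.any(np.diff(self.breath_end_time) <= 0):
            raise ValueError("breath_end_time must be strictly increasing")
        if np.any((self.petco2 < 0) | (self.petco2 > 100)):
            raise ValueError("petco2 outside the physiological range [0, 100] mmHg")
        for (a0, a1), (b0, b1) in zip(self.hold_windows, self.hold_windows[1:]):
            if b0 < a1:
                raise ValueError("hold windows must be non-overlapping and sorted")


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma hemodynamic response function parameters.

    The canonical shape: 6 s peak, 16 s undershoot, unit dispersions,
    undershoot one sixth of the peak, 32 s support, sampled at ``dt``.
    The kernel is normalized to unit area (scale invariance).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    dt: float = 0.1
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "dt",
            "duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def kernel(self) -> np.ndarray:
        """Unit-area double-gamma kernel sampled every ``dt`` seconds."""
        t = np.arange(0.0, self.duration, self.dt)
        peak = gamma_dist.pdf(
            t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        h = peak - under / self.undershoot_ratio
        return h / (h.sum() * self.dt)


@dataclass
class UniformSeries:
    """A uniformly sampled series: values at ``t0 + i*dt``."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt


@dataclass
class Co2Regressor:
    """Frame-aligned CO2 model (mmHg) with the temporal shift that produced it."""

    values: np.ndarray
    tr: float
    applied_delay: float
    n_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_frames:
            raise ValueError("values length must equal n_frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor values must be finite")


def detect_end_tidal(
    trace: CapnoTrace,
    paradigm: Paradigm | None = None,
    *,
    smooth_window_s: float = 0.25,
    min_interval_s: float = 1.5,
    min_prominence: float = 1.0,
    value_window_s: float = 0.1,
) -> EndTidalSeries:
    """Locate the end of every breath and read off its end-tidal pCO2.

    The trace is lightly smoothed (moving average of ``smooth_window_s``) and
    expiratory maxima are found by prominence-based peak picking with a
    minimum inter-breath interval; candidate breaths closer together than
    ``min_interval_s`` are merged into one. The reported PETCO2 is the raw
    local maximum within ``value_window_s`` of each smoothed peak, so
    noiseless waveform maxima are recovered exactly. The first peak after a
    hold window is, by construction of the task, the quick-exhalation value.
    """
    if trace.sampling_rate < 10:
        raise ValueError("capnograph sampling rate must be >= 10 Hz")
    if paradigm is not None and trace.time[-1] < paradigm.total_s - 1.0 / trace.sampling_rate:
        raise CoverageError(
            f"trace ends at {trace.time[-1]:.1f} s but the paradigm lasts "
            f"{paradigm.total_s:.1f} s"
        )
    if np.ptp(trace.pco2) < min_prominence:
        raise NoBreathsError("trace is flat: no breath excursions above prominence")

    fs = trace.sampling_rate
    win = max(1, int(round(smooth_window_s * fs)))
    kernel = np.ones(win) / win
    # edge-value padding: zero-padding would fabricate maxima at the ends
    padded = np.pad(trace.pco2, (win // 2, win - 1 - win // 2), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")

    peaks, _ = find_peaks(
        smoothed,
        distance=max(1, int(round(min_interval_s * fs))),
        prominence=min_prominence,
    )
    if peaks.size == 0:
        raise NoBreathsError("no breaths detected in capnograph trace")

    half = max(1, int(round(value_window_s * fs)))
    times = np.empty(peaks.size)
    values = np.empty(peaks.size)
    for k, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(trace.pco2.size, p + half + 1)
        j = lo + int(np.argmax(trace.pco2[lo:hi]))
        times[k] = trace.time[j]
        values[k] = trace.pco2[j]

    holds = paradigm.hold_windows() if paradigm is not None else []
    return EndTidalSeries(times, values, holds)


def interpolate_breath_hold(
    ets: EndTidalSeries,
    dt: float = 0.1,
    t_end: float | None = None,
) -> UniformSeries:
    """Piecewise-linear PETCO2 trace on a uniform grid.

    Within each breath-hold window the trace is the straight line between the
    final pre-hold end-tidal value and the post-hold quick-exhalation value;
    between ordinary breaths it interpolates linearly between successive
    end-tidal values. Any spurious detection strictly inside a hold window is
    discarded first. Values before the first / after the last breath are held
    constant.
    """
    times = ets.breath_end_time
    vals = ets.petco2

    keep = np.ones(times.size, dtype=bool)
    for start, end in ets.hold_windows:
        keep &= ~((times > start) & (times < end))
    times, vals = times[keep], vals[keep]
    if times.size < 2:
        raise NoBreathsError("fewer than two end-tidal values after hold filtering")

    for start, end in ets.hold_windows:
        if not np.any(times >= end):
            raise UnboundedHoldError(
                f"hold window ({start:.1f}, {end:.1f}) s has no post-hold breath"
            )
        if not np.any(times <= start):
            raise UnboundedHoldError(
                f"hold window ({start:.1f}, {end:.1f}) s has no pre-hold breath"
            )

    stop = times[-1] if t_end is None else t_end
    grid = np.arange(0.0, stop + dt / 2, dt)
    return UniformSeries(np.interp(grid, times, vals), dt=dt, t0=0.0)


def convolve_hrf(series: UniformSeries, hrf: HrfSpec | None = None) -> UniformSeries:
    """Causal convolution with the unit-area double-gamma HRF.

    The input is padded on the left with its first value so that a constant
    input stays exactly constant (and a sustained step of A mmHg converges to
    A mmHg once the kernel support has passed).
    """
    hrf = hrf or HrfSpec()
    if abs(series.dt - hrf.dt) > 1e-9:
        raise ResolutionError(
            f"series dt {series.dt} does not match kernel dt {hrf.dt}"
        )
    h = hrf.kernel()
    x = series.values
    padded = np.concatenate([np.full(h.size - 1, x[0]), x])
    y = np.convolve(padded, h, mode="valid") * hrf.dt
    return UniformSeries(y, dt=series.dt, t0=series.t0)


def resample_to_frames(
    series: UniformSeries,
    tr: float,
    n_frames: int,
    delay: float = 0.0,
    t0: float = 0.0,
) -> Co2Regressor:
    """Shift a uniform series by ``delay`` and sample at BOLD frame midpoints.

    Frame k is sampled at ``t0 + (k + 0.5) * tr - delay``; samples falling
    outside the series take the nearest boundary value (constant padding).
    ``t0`` accounts for discarded leading frames.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    frame_t = t0 + (np.arange(n_frames) + 0.5) * tr
    vals = np.interp(frame_t - delay, series.t, series.values)
    return Co2Regressor(vals, tr=tr, applied_delay=delay, n_frames=n_frames)


class RegressorBuilder:
    """Factory producing frame-aligned CO2 regressors at arbitrary delays.

    Wraps the 0.1 s-resolution HRF-convolved end-tidal series so delay
    optimization can shift at full resolution before TR sampling.
    """

    def __init__(
        self, series: UniformSeries, tr: float, n_frames: int, t0: float = 0.0
    ) -> None:
        self.series = series
        self.tr = tr
        self.n_frames = n_frames
        self.t0 = t0
        self._frame_t = t0 + (np.arange(n_frames) + 0.5) * tr

    def values(self, delay: float) -> np.ndarray:
        return np.interp(self._frame_t - delay, self.series.t, self.series.values)

    def at_delay(self, delay: float) -> Co2Regressor:
        return Co2Regressor(
            self.values(delay), tr=self.tr, applied_delay=delay, n_frames=self.n_frames
        )

    def matrix(self, delays: np.ndarray) -> np.ndarray:
        """Regressors at many delays, shape (n_delays, n_frames)."""
        return np.stack([self.values(d) for d in np.atleast_1d(delays)])


def build_regressor_series(
    trace: CapnoTrace,
    paradigm: Paradigm,
    hrf: HrfSpec | None = None,
    **detect_kwargs,
) -> UniformSeries:
    """Full capnometry chain: detect breaths, interpolate holds, convolve HRF."""
    hrf = hrf or HrfSpec()
    ets = detect_end_tidal(trace, paradigm, **detect_kwargs)
    interp = interpolate_breath_hold(ets, dt=hrf.dt)
    return convolve_hrf(interp, hrf)
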