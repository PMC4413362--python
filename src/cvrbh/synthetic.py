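"""Synthetic capnograph traces and 4D BOLD stroke phantoms with known truth.

The generator emulates the 6-cycle breath-hold study conditions: a 200 Hz
capnograph whose expiratory maxima sit at a 40 mmHg baseline with an 8 mmHg
post-hold boost, and a left-lateralized stroke phantom on a 32×38×32 grid of
3.5×3.5×3 mm voxels whose regional CVR truth is 0.29 (healthy), 0.21
(peri-infarct) and 0.19 (lesion) %BOLD/mmHg, with hemodynamic delays of
+1.2 s in the peri-infarct shell and +1.8 s in the lesion on top of a +4 s
bulk CO2→BOLD transit delay. Linear drift, white voxel noise and an optional
shared ("global") noise component complete the forward model

    y_v(t) = B · (1 + [cvr_v · Δx(t − delay_v) + drift·(t − t̄)
                        + shared(t) + ε_v(t)] / 100),

where Δx is the HRF-convolved end-tidal CO2 excursion about its mean. Signal
terms are centred on the temporal mean so that %BOLD conversion inverts the
model exactly and noiseless parameter recovery is an identity check.

All randomness flows from a single integer seed per call; a fixed seed gives
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bold import BoldRun
from .capnometry import CapnoTrace, RegressorBuilder, UniformSeries
from .masks import MaskSet, build_mask_set, centered_vox2std
from .paradigm import Paradigm, make_paradigm

__all__ = [
    "Paradigm",
    "make_paradigm",
    "PhantomTruth",
    "simulate_capnograph",
    "make_stroke_phantom",
    "simulate_bold",
    "shared_noise_sd_for_global_r2",
]

#: regional defaults reported for stroke cohorts, %BOLD per mmHg
HEALTHY_CVR = 0.29
PERI_CVR = 0.21
LESION_CVR = 0.19
#: regional hemodynamic delay offsets, s
PERI_DELAY_OFFSET = 1.2
LESION_DELAY_OFFSET = 1.8
#: bulk CO2-to-brain transit + sampling-line delay, s
BULK_DELAY = 4.0


@dataclass
class PhantomTruth:
    """Ground truth underlying one synthetic stroke phantom."""

    cvr_map: np.ndarray
    delay_map: np.ndarray
    brain: np.ndarray
    masks: MaskSet
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    noise_sd: float = 0.5
    drift_slope: float = 0.01
    baseline_petco2: float = 40.0
    hold_boost: float = 8.0
    seed: int = 0
    region_cvr: dict[str, float] = field(default_factory=dict)

    def labels(self) -> dict[str, np.ndarray]:
        """Region label masks partitioning the phantom brain."""
        m = self.masks
        return {
            "l_healthy": m.l_healthy,
            "l_peri_infarct": m.l_peri_infarct,
            "l_lesion": m.l_lesion,
            "r_healthy": m.r_healthy,
            "r_peri_infarct": m.r_peri_infarct,
            "r_lesion": m.r_lesion,
            "l_hemi": m.l_hemi,
            "r_hemi": m.r_hemi,
        }


def _breath_segment(
    duration: float,
    breath_rate: float,
    peaks: np.ndarray,
    insp_level: float,
    fs: float,
) -> np.ndarray:
    """Capnogram of whole breaths filling ``duration`` seconds.

    Each breath is a raised-cosine excursion from the inspiratory level to
    its assigned end-tidal peak, so the waveform maximum equals the peak
    value exactly and the segment starts and ends at the inspiratory level
    (end-expiration, ready for a hold).
    """
    n_samples = int(round(duration * fs))
    n_breaths = max(1, int(round(duration * breath_rate)))
    t = np.arange(n_samples) / fs
    period = duration / n_breaths
    idx = np.minimum((t / period).astype(int), n_breaths - 1)
    phase = (t - idx * period) / period
    shape = 0.5 - 0.5 * np.cos(2 * np.pi * phase)
    return insp_level + (peaks[idx] - insp_level) * shape


def simulate_capnograph(
    paradigm: Paradigm | None = None,
    baseline_petco2: float = 40.0,
    hold_boost: float = 8.0,
    breath_rate: float = 0.25,
    noise_sd: float = 0.2,
    seed: int | None = None,
    fs: float = 200.0,
    insp_level: float = 4.0,
    boost_tau: float = 12.0,
    tail_s: float = 10.0,
) -> CapnoTrace:
    """Synthesize a breath-hold capnograph trace.

    Natural and paced segments contain regular breaths whose expiratory
    maxima equal ``baseline_petco2``; during each hold the trace stays flat
    at the inspiratory level (no airflow); the first breath after a hold
    peaks at exactly ``baseline_petco2 + hold_boost`` ("quick exhalation"),
    with subsequent peaks relaxing back to baseline with time constant
    ``boost_tau``. ``tail_s`` of recovery breathing is appended after the
    last hold so the final boost is observable. White sensor noise of
    ``noise_sd`` mmHg is added and the trace clipped at 0.
    """
    p = paradigm or Paradigm()
    if breath_rate * p.paced_s < 1:
        raise ValueError("breath_rate too slow for the paced segment")

    def seg_peaks(duration: float, since_hold: float | None) -> np.ndarray:
        n = max(1, int(round(duration * breath_rate)))
        peaks = np.full(n, baseline_petco2)
        if since_hold is not None:
            peaks[0] = baseline_petco2 + hold_boost
            period = duration / n
            t_rel = np.arange(1, n) * period
            peaks[1:] = baseline_petco2 + hold_boost * np.exp(-t_rel / boost_tau)
        return peaks

    chunks = []
    for cyc in range(p.n_cycles):
        post_hold = None if cyc == 0 else 0.0
        chunks.append(
            _breath_segment(p.natural_s, breath_rate,
                            seg_peaks(p.natural_s, post_hold), insp_level, fs)
        )
        chunks.append(
            _breath_segment(p.paced_s, breath_rate,
                            seg_peaks(p.paced_s, None), insp_level, fs)
        )
        chunks.append(np.full(int(round(p.hold_s * fs)), float(insp_level)))
    chunks.append(
        _breath_segment(tail_s, breath_rate, seg_peaks(tail_s, 0.0), insp_level, fs)
    )
    pco2 = np.concatenate(chunks)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pco2 = pco2 + rng.normal(0.0, noise_sd, pco2.size)
    time = np.arange(pco2.size) / fs
    return CapnoTrace(time=time, pco2=np.clip(pco2, 0.0, None), sampling_rate=fs)


def make_stroke_phantom(
    shape: tuple[int, int, int] = (32, 38, 32),
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 3.0),
    lesion_center_mm: tuple[float, float, float] | None = (-28.0, 4.0, 6.0),
    lesion_radius_mm: float = 14.0,
    peri_radius_mm: float = 10.0,
    healthy_cvr: float = HEALTHY_CVR,
    peri_cvr: float = PERI_CVR,
    lesion_cvr: float = LESION_CVR,
    bulk_delay: float = BULK_DELAY,
    peri_delay_offset: float = PERI_DELAY_OFFSET,
    lesion_delay_offset: float = LESION_DELAY_OFFSET,
    left_healthy_cvr: float | None = None,
    cvr_jitter_sd: float = 0.0,
    delay_jitter_sd: float = 0.0,
    noise_sd: float = 0.5,
    drift_slope: float = 0.01,
    baseline_petco2: float = 40.0,
    hold_boost: float = 8.0,
    seed: int = 0,
) -> PhantomTruth:
    """Build the ground truth of a left-lateralized stroke phantom.

    A midline-symmetric ellipsoidal brain holds a spherical lesion in the
    left hemisphere; the peri-infarct shell is generated through the same
    mask algebra the analysis uses, guaranteeing round-trip consistency.
    Right-hemisphere homologue regions carry healthy values (the
    contralesional side is unaffected); ``left_healthy_cvr`` lets the
    ipsilesional healthy tissue deviate from the right. ``lesion_center_mm``
    of None gives a lesion-free control phantom with uniform CVR.
    """
    shape = tuple(int(s) for s in shape)
    vox2std = centered_vox2std(shape, voxel_size_mm)

    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    world = [
        vox2std[i, i] * grids[i] + vox2std[i, 3] for i in range(3)
    ]
    semi = [0.45 * n * v for n, v in zip(shape, voxel_size_mm)]
    brain = sum((w / s) ** 2 for w, s in zip(world, semi)) <= 1.0

    if lesion_center_mm is not None:
        d2 = sum((w - c) ** 2 for w, c in zip(world, lesion_center_mm))
        lesion = (d2 <= lesion_radius_mm**2) & brain
    else:
        lesion = np.zeros(shape, dtype=bool)

    masks = build_mask_set(
        brain, lesion, affine=vox2std, affine_to_std=vox2std,
        radius_mm=peri_radius_mm,
    )

    lh_cvr = healthy_cvr if left_healthy_cvr is None else left_healthy_cvr
    cvr = np.zeros(shape)
    cvr[brain] = healthy_cvr
    cvr[masks.l_healthy] = lh_cvr
    cvr[masks.l_peri_infarct] = peri_cvr
    cvr[masks.l_lesion] = lesion_cvr

    delay = np.zeros(shape)
    delay[brain] = bulk_delay
    delay[masks.l_peri_infarct] = bulk_delay + peri_delay_offset
    delay[masks.l_lesion] = bulk_delay + lesion_delay_offset

    if cvr_jitter_sd > 0 or delay_jitter_sd > 0:
        rng = np.random.default_rng(seed)
        if cvr_jitter_sd > 0:
            cvr[brain] += rng.normal(0.0, cvr_jitter_sd, int(brain.sum()))
        if delay_jitter_sd > 0:
            delay[brain] += rng.normal(0.0, delay_jitter_sd, int(brain.sum()))

    return PhantomTruth(
        cvr_map=cvr, delay_map=delay, brain=brain, masks=masks,
        affine=vox2std, voxel_size_mm=tuple(voxel_size_mm),
        noise_sd=noise_sd, drift_slope=drift_slope,
        baseline_petco2=baseline_petco2, hold_boost=hold_boost, seed=seed,
        region_cvr={
            "healthy": healthy_cvr, "l_healthy": lh_cvr,
            "peri_infarct": peri_cvr, "lesion": lesion_cvr,
        },
    )


def _centered_signal(
    truth: PhantomTruth,
    builder: RegressorBuilder,
    delay_step: float = 0.1,
) -> np.ndarray:
    """Noise-free per-voxel %BOLD signal (n_brain_voxels, n_frames)."""
    n_frames = builder.n_frames
    cvr = truth.cvr_map[truth.brain]
    delays = truth.delay_map[truth.brain]
    dq = np.round(delays / delay_step) * delay_step
    sig = np.empty((cvr.size, n_frames))
    for d in np.unique(dq):
        x = builder.values(d)
        rows = dq == d
        sig[rows] = cvr[rows, None] * (x - x.mean())[None, :]
    return sig


def simulate_bold(
    truth: PhantomTruth,
    co2: UniformSeries,
    paradigm: Paradigm | None = None,
    tr: float | None = None,
    drop_first: int = 1,
    noise_sd: float | None = None,
    shared_noise_sd: float = 0.0,
    seed: int | None = None,
    baseline: float = 1000.0,
) -> BoldRun:
    """Generate a raw-intensity 4D BOLD run from a phantom truth.

    Per-voxel hemodynamic delays are applied to the HRF-convolved CO2 series
    at its native 0.1 s resolution before TR sampling. The shared noise
    component (one series added to every brain voxel, used to calibrate the
    global-signal fit quality) is residualized against {1, t, bulk-delay
    regressor} so it is stimulus-independent by construction, then rescaled
    to the requested sd.
    """
    p = paradigm or Paradigm()
    tr = p.tr if tr is None else tr
    n_frames = p.n_frames(tr, drop_first)
    builder = RegressorBuilder(co2, tr=tr, n_frames=n_frames, t0=drop_first * tr)
    if co2.t[-1] < p.total_s - tr:
        raise ValueError("CO2 series does not cover the run")

    sig = _centered_signal(truth, builder)
    t_idx = np.arange(n_frames, dtype=float)
    drift = truth.drift_slope * (t_idx - t_idx.mean())

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    nsd = truth.noise_sd if noise_sd is None else noise_sd
    percent = sig + drift[None, :]
    if shared_noise_sd > 0:
        shared = rng.normal(0.0, 1.0, n_frames)
        bulk = float(np.median(truth.delay_map[truth.brain]))
        x = builder.values(bulk)
        design = np.column_stack([np.ones(n_frames), t_idx - t_idx.mean(),
                                  x - x.mean()])
        shared -= design @ np.linalg.lstsq(design, shared, rcond=None)[0]
        shared *= shared_noise_sd / shared.std()
        percent = percent + shared[None, :]
    if nsd > 0:
        percent = percent + rng.normal(0.0, nsd, percent.shape)

    data = np.zeros(truth.brain.shape + (n_frames,))
    data[truth.brain] = baseline * (1.0 + percent / 100.0)
    return BoldRun(data, tr=tr, affine=truth.affine, brain_mask=truth.brain)


def shared_noise_sd_for_global_r2(
    truth: PhantomTruth,
    co2: UniformSeries,
    paradigm: Paradigm | None = None,
    target_r2: float = 0.38,
    tr: float | None = None,
    drop_first: int = 1,
) -> float:
    """Shared-noise sd that sets the global-signal fit R² near ``target_r2``.

    The global signal is the brain mean of the noise-free signal plus the
    shared component (independent voxel noise averages away over thousands
    of voxels), so sd_shared = sd_signal · sqrt((1−R²)/R²).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    p = paradigm or Paradigm()
    tr = p.tr if tr is None else tr
    n_frames = p.n_frames(tr, drop_first)
    builder = RegressorBuilder(co2, tr=tr, n_frames=n_frames, t0=drop_first * tr)
    g = _centered_signal(truth, builder).mean(axis=0)
    # remove the linear component, as preprocessing will
    t = np.arange(n_frames) - (n_frames - 1) / 2
    g = g - (g @ t) / (t @ t) * t
    sd_signal = g.std()
    return float(sd_signal * np.sqrt((1 - target_r2) / target_r2))
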