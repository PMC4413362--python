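"""Voxelwise CVR estimation: the GlobOpt, VoxOpt and RHsig analyses.

All three estimators fit a one-regressor GLM (intercept + model) to every
in-mask voxel of a prepared %BOLD run; they differ in where the model comes
from and how hemodynamic delay is handled:

* :class:`GlobOptCvr` — the end-tidal CO2 regressor, delay-optimized once
  against the global BOLD signal over a ±15 s grid in 0.1 s steps; betas are
  %BOLD per mmHg.
* :class:`VoxOptCvr` — the same regressor, but the delay is re-optimized per
  voxel on a grid of offsets around the global optimum; the per-voxel best
  delay is stored alongside beta and R².
* :class:`RHsigCvr` — no CO2 trace: the mean %BOLD series over a reference
  (contralesional-hemisphere) mask is the model, and betas are expressed as a
  percentage of that reference amplitude (100% = same amplitude).

The estimators follow scikit-learn conventions (``fit``, fitted attributes
with a trailing underscore, ``get_params``/``set_params``); the module-level
``fit_*`` functions are thin wrappers around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .bold import BoldRun, global_signal
from .capnometry import Co2Regressor, RegressorBuilder
from .errors import DegenerateRegressorError, DelayRangeWarning, SearchFailureError

__all__ = [
    "DelaySearchSpec",
    "CvrResult",
    "GlobOptCvr",
    "VoxOptCvr",
    "RHsigCvr",
    "fit_glm_single",
    "optimize_global_delay",
    "fit_globopt",
    "fit_voxopt",
    "fit_rhsig",
]


@dataclass(frozen=True)
class DelaySearchSpec:
    """Exhaustive delay grid: default −15 s to +15 s in 0.1 s steps."""

    min_delay: float = -15.0
    max_delay: float = 15.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.min_delay >= self.max_delay:
            raise ValueError("min_delay must be < max_delay")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def delays(self) -> np.ndarray:
        """Grid values, computed in integer steps so 0.0 is exactly on grid."""
        lo = int(np.ceil(self.min_delay / self.step - 1e-9))
        hi = int(np.floor(self.max_delay / self.step + 1e-9))
        return np.arange(lo, hi + 1) * self.step


@dataclass
class CvrResult:
    """Per-voxel output of one CVR analysis.

    ``beta`` is %BOLD/mmHg for GlobOpt and VoxOpt, and % of the reference
    amplitude for RHsig. ``delay`` is the per-voxel absolute delay map (s),
    present only for VoxOpt; GlobOpt records only the scalar
    ``global_delay``.
    """

    method: str
    beta: np.ndarray
    r2: np.ndarray
    mask: np.ndarray
    delay: np.ndarray | None = None
    rel_delay: np.ndarray | None = None
    global_delay: float | None = None
    global_r2: float | None = None


def fit_glm_single(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """OLS of ``y`` on [intercept, ``x``]: returns (slope, R²)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("y and x must have equal length >= 3")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise DegenerateRegressorError("regressor is constant")
    yc = y - y.mean()
    beta = (xc @ yc) / sxx
    syy = yc @ yc
    r2 = 0.0 if syy == 0 else float(beta * beta * sxx / syy)
    return float(beta), r2


def _mass_glm(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-regressor OLS for many voxels. Y is (n_voxels, n_frames)."""
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise DegenerateRegressorError("regressor is constant")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    beta = num / sxx
    syy = np.einsum("ij,ij->i", Yc, Yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, beta * beta * sxx / syy, 0.0)
    return beta, r2


def _grid_glm(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-voxels-by-all-delays OLS pieces.

    Returns (num, sxx, r2) where ``num[v, d]`` is the centered cross product,
    ``sxx[d]`` the regressor sum of squares and ``r2[v, d]`` the variance
    explained. beta = num / sxx.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    if np.any(sxx == 0):
        raise DegenerateRegressorError("a shifted regressor is constant")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ Xc.T
    syy = np.einsum("ij,ij->i", Yc, Yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(
            syy[:, None] > 0, num * num / (syy[:, None] * sxx[None, :]), 0.0
        )
    return num, sxx, r2


def _detrend_rows(X: np.ndarray) -> np.ndarray:
    """Remove each row's least-squares linear trend (centered time axis).

    The BOLD data are linearly detrended upstream, so the design must receive
    the identical temporal preprocessing: fitting a detrended voxel series on
    a regressor that still carries its own drift component attenuates the
    slope by the squared regressor–time correlation.
    """
    X = np.atleast_2d(X)
    t = np.arange(X.shape[1], dtype=float)
    tc = t - t.mean()
    slope = (X @ tc) / (tc @ tc)
    return X - slope[:, None] * tc


def _abs_order(delays: np.ndarray) -> np.ndarray:
    """Index order scanning delays by increasing |delay| (ties: negative first),
    so a first-occurrence argmax breaks R² ties toward the smallest shift."""
    return np.lexsort((delays, np.abs(delays)))


def optimize_global_delay(
    builder: RegressorBuilder,
    gs: np.ndarray,
    spec: DelaySearchSpec | None = None,
    detrend_design: bool = True,
) -> tuple[float, float]:
    """Grid-search the delay maximizing R² against the global BOLD signal.

    Ties are broken toward the smallest absolute delay; a warning is emitted
    when the optimum sits on a search boundary (the true delay may be
    outside the grid). ``detrend_design`` applies the same linear detrending
    to the shifted regressors that preprocessing applied to the data.
    """
    spec = spec or DelaySearchSpec()
    gs = np.asarray(gs, dtype=float)
    if gs.size < 3:
        raise ValueError("global signal must have at least 3 frames")
    delays = spec.delays()
    order = _abs_order(delays)
    X = builder.matrix(delays[order])
    if detrend_design:
        X = _detrend_rows(X)
    try:
        _, _, r2 = _grid_glm(gs[None, :], X)
    except DegenerateRegressorError as exc:
        raise SearchFailureError("all delay fits degenerate") from exc
    r2 = r2[0]
    best = int(np.argmax(r2))
    delay = float(delays[order][best])
    if delay <= delays.min() + spec.step / 2 or delay >= delays.max() - spec.step / 2:
        warnings.warn(
            f"optimal global delay {delay:+.1f} s is at the search boundary",
            DelayRangeWarning,
        )
    return delay, float(r2[best])


class GlobOptCvr(BaseEstimator):
    """Globally delay-optimized CO2 GLM (the standard breath-hold analysis).

    Parameters are the global delay-search grid bounds and step in seconds.
    After ``fit``: ``beta_`` (%BOLD/mmHg), ``r2_`` (3D maps), ``global_delay_``
    and ``global_r2_``.
    """

    def __init__(self, min_delay: float = -15.0, max_delay: float = 15.0,
                 step: float = 0.1, detrend_design: bool = True):
        self.min_delay = min_delay
        self.max_delay = max_delay
        self.step = step
        self.detrend_design = detrend_design

    def fit(self, run: BoldRun, builder: RegressorBuilder) -> "GlobOptCvr":
        spec = DelaySearchSpec(self.min_delay, self.max_delay, self.step)
        gs = global_signal(run)
        self.global_delay_, self.global_r2_ = optimize_global_delay(
            builder, gs, spec, detrend_design=self.detrend_design
        )
        x = builder.values(self.global_delay_)
        if self.detrend_design:
            x = _detrend_rows(x)[0]
        beta, r2 = _mass_glm(run.data[run.brain_mask], x)
        self.beta_ = np.zeros(run.data.shape[:3])
        self.r2_ = np.zeros(run.data.shape[:3])
        self.beta_[run.brain_mask] = beta
        self.r2_[run.brain_mask] = r2
        self.mask_ = run.brain_mask
        return self

    def result(self) -> CvrResult:
        return CvrResult(
            method="GlobOpt", beta=self.beta_, r2=self.r2_, mask=self.mask_,
            global_delay=self.global_delay_, global_r2=self.global_r2_,
        )


class VoxOptCvr(BaseEstimator):
    """Per-voxel delay-optimized CO2 GLM.

    The voxel search runs over offsets ``rel_min..rel_max`` (s, step ``step``)
    relative to the globally optimized delay; because offset 0 is always on
    the grid, every voxel's R² dominates its GlobOpt R². ``global_*`` bounds
    control the initial global-signal search.
    """

    def __init__(self, rel_min: float = -15.0, rel_max: float = 15.0,
                 step: float = 0.1, global_min: float = -15.0,
                 global_max: float = 15.0, detrend_design: bool = True):
        self.rel_min = rel_min
        self.rel_max = rel_max
        self.step = step
        self.global_min = global_min
        self.global_max = global_max
        self.detrend_design = detrend_design

    def fit(
        self,
        run: BoldRun,
        builder: RegressorBuilder,
        global_delay: float | None = None,
    ) -> "VoxOptCvr":
        if global_delay is None:
            gspec = DelaySearchSpec(self.global_min, self.global_max, self.step)
            global_delay, self.global_r2_ = optimize_global_delay(
                builder, global_signal(run), gspec,
                detrend_design=self.detrend_design,
            )
        else:
            self.global_r2_ = None
        self.global_delay_ = float(global_delay)

        offsets = DelaySearchSpec(self.rel_min, self.rel_max, self.step).delays()
        order = _abs_order(offsets)
        scanned = offsets[order]
        X = builder.matrix(self.global_delay_ + scanned)
        if self.detrend_design:
            X = _detrend_rows(X)
        Y = run.data[run.brain_mask]
        num, sxx, r2 = _grid_glm(Y, X)
        best = np.argmax(r2, axis=1)  # first max -> smallest |offset|
        rows = np.arange(Y.shape[0])
        shape = run.data.shape[:3]
        self.beta_ = np.zeros(shape)
        self.r2_ = np.zeros(shape)
        self.delay_ = np.zeros(shape)
        self.rel_delay_ = np.zeros(shape)
        self.beta_[run.brain_mask] = num[rows, best] / sxx[best]
        self.r2_[run.brain_mask] = r2[rows, best]
        self.rel_delay_[run.brain_mask] = scanned[best]
        self.delay_[run.brain_mask] = self.global_delay_ + scanned[best]
        self.mask_ = run.brain_mask
        return self

    def result(self) -> CvrResult:
        return CvrResult(
            method="VoxOpt", beta=self.beta_, r2=self.r2_, mask=self.mask_,
            delay=self.delay_, rel_delay=self.rel_delay_,
            global_delay=self.global_delay_, global_r2=self.global_r2_,
        )


class RHsigCvr(BaseEstimator):
    """Reference-hemisphere signal regression (no CO2 trace required).

    The model is the mean %BOLD series over ``reference_mask`` with its 100
    baseline removed; betas are scaled ×100 so a voxel identical to the
    reference series scores exactly 100%.
    """

    def fit(self, run: BoldRun, reference_mask: np.ndarray) -> "RHsigCvr":
        ref = np.asarray(reference_mask, dtype=bool) & run.brain_mask
        if not np.any(ref):
            raise ValueError("reference mask is empty (or outside the brain mask)")
        x = run.data[ref].mean(axis=0) - 100.0
        beta, r2 = _mass_glm(run.data[run.brain_mask], x)
        shape = run.data.shape[:3]
        self.beta_ = np.zeros(shape)
        self.r2_ = np.zeros(shape)
        self.beta_[run.brain_mask] = beta * 100.0
        self.r2_[run.brain_mask] = r2
        self.mask_ = run.brain_mask
        self.reference_series_ = x + 100.0
        return self

    def result(self) -> CvrResult:
        return CvrResult(
            method="RHsig", beta=self.beta_, r2=self.r2_, mask=self.mask_,
        )


def fit_globopt(
    run: BoldRun, regressor: Co2Regressor, detrend_design: bool = True
) -> CvrResult:
    """GLM of every in-mask voxel on an already delay-optimized regressor."""
    x = regressor.values
    if detrend_design:
        x = _detrend_rows(x)[0]
    beta, r2 = _mass_glm(run.data[run.brain_mask], x)
    shape = run.data.shape[:3]
    bmap = np.zeros(shape)
    rmap = np.zeros(shape)
    bmap[run.brain_mask] = beta
    rmap[run.brain_mask] = r2
    return CvrResult(
        method="GlobOpt", beta=bmap, r2=rmap, mask=run.brain_mask,
        global_delay=regressor.applied_delay,
    )


def fit_voxopt(
    run: BoldRun,
    builder: RegressorBuilder,
    spec: DelaySearchSpec | None = None,
    global_delay: float | None = None,
) -> CvrResult:
    """Per-voxel delay-optimized fit (see :class:`VoxOptCvr`)."""
    spec = spec or DelaySearchSpec()
    est = VoxOptCvr(rel_min=spec.min_delay, rel_max=spec.max_delay, step=spec.step)
    return est.fit(run, builder, global_delay=global_delay).result()


def fit_rhsig(run: BoldRun, reference_mask: np.ndarray) -> CvrResult:
    """Reference-hemisphere regression (see :class:`RHsigCvr`)."""
    return RHsigCvr().fit(run, reference_mask).result()
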