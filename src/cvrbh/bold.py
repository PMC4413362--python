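"""BOLD run preparation: %BOLD conversion, linear detrending, global signal,
and head-motion summary.

The run is assumed motion-corrected upstream; no spatial smoothing is applied
anywhere in this module, so CVR values cannot bleed between neighbouring
voxels (important around an infarct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskWarning

__all__ = [
    "BoldRun",
    "MotionParams",
    "auto_brain_mask",
    "to_percent_bold",
    "detrend_linear",
    "global_signal",
    "framewise_displacement",
]


@dataclass
class BoldRun:
    """A 4D BOLD series (x, y, z, frame) with its TR, affine and brain mask."""

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.data.shape[3] < 10:
            raise ValueError("run must have at least 10 frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain_mask shape must match the spatial grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionParams:
    """Rigid-body motion per frame: translations (mm) and rotations (radians)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


def auto_brain_mask(raw: np.ndarray) -> np.ndarray:
    """Otsu threshold on the temporal-mean image, for runs without a mask."""
    from skimage.filters import threshold_otsu

    mean_img = np.asarray(raw, dtype=float).mean(axis=3)
    return mean_img > threshold_otsu(mean_img)


def to_percent_bold(
    raw: np.ndarray,
    brain_mask: np.ndarray | None,
    tr: float,
    affine: np.ndarray | None = None,
) -> BoldRun:
    """Divide each in-mask voxel by its temporal mean and scale to 100.

    With ``brain_mask=None`` an Otsu threshold on the temporal-mean image is
    used. Voxels inside the mask with non-positive temporal mean cannot be
    normalized; they are dropped from the mask with a warning. Out-of-mask
    voxels are zeroed.
    """
    raw = np.asarray(raw, dtype=float)
    if brain_mask is None:
        brain_mask = auto_brain_mask(raw)
    mask = np.asarray(brain_mask, dtype=bool).copy()
    means = raw.mean(axis=3)
    bad = mask & (means <= 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} in-mask voxels with non-positive mean removed",
            EmptyMaskWarning,
        )
        mask &= ~bad
    data = np.zeros_like(raw)
    data[mask] = raw[mask] / means[mask][:, None] * 100.0
    return BoldRun(data, tr=tr, affine=np.eye(4) if affine is None else affine,
                   brain_mask=mask)


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove each voxel's least-squares linear drift, preserving its mean.

    The fit uses a centered time axis so the 100-%BOLD baseline is untouched;
    refitting a line to the output gives slope 0 to numerical precision, which
    also makes the operation idempotent.
    """
    if run.n_frames < 3:
        raise ValueError("need at least 3 frames to detrend")
    t = np.arange(run.n_frames, dtype=float)
    tc = t - t.mean()
    denom = tc @ tc
    data = run.data.copy()
    y = data[run.brain_mask]
    slope = (y @ tc) / denom
    data[run.brain_mask] = y - slope[:, None] * tc
    return BoldRun(data, tr=run.tr, affine=run.affine, brain_mask=run.brain_mask)


def global_signal(run: BoldRun) -> np.ndarray:
    """Per-frame mean of the in-mask voxel series (%BOLD)."""
    if not np.any(run.brain_mask):
        raise ValueError("brain mask is empty")
    return run.data[run.brain_mask].mean(axis=0)


def framewise_displacement(
    mp: MotionParams, head_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Frame-wise displacement (Power): sum of absolute frame-to-frame motion.

    Rotations are converted to arc length on a sphere of ``head_radius`` mm.
    The first frame has FWD 0 by convention; the mean is over frames 2..N.
    Returns (per-frame FWD in mm, mean FWD).
    """
    if mp.n_frames < 2:
        raise ValueError("need at least 2 frames for framewise displacement")
    params = np.hstack([mp.translations, mp.rotations * head_radius])
    fwd = np.concatenate([[0.0], np.abs(np.diff(params, axis=0)).sum(axis=1)])
    return fwd, float(fwd[1:].mean())
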