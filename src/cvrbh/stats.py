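"""Regional summaries and group comparisons of CVR maps.

A voxel only enters a regional average if its GLM explained more variance
than expected by chance: the R² threshold is the P = 0.05 point of the null
distribution of R² for a one-regressor GLM with the run's number of frames
(R² = 0.0288 for the canonical 134-frame run). Summaries per mask report the
percentage of voxels passing, and the mean R², beta and delay over passing
voxels; comparisons use Student (paired / one-sample) and Welch (unpaired)
t-tests with no multiple-comparison correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cvr import CvrResult
from .errors import EmptyMaskWarning, GridMismatchError

__all__ = [
    "ThresholdSpec",
    "RegionSummary",
    "CompareResult",
    "critical_r2",
    "threshold_by_r2",
    "summarize_mask",
    "delay_difference",
    "compare",
]


def critical_r2(n_frames: int, alpha: float = 0.05) -> float:
    """Chance-level R² threshold for a one-regressor GLM.

    With n frames the F statistic of the fit is F(1, n−2) under the null, so
    the (1−alpha) critical R² is F_crit / (F_crit + n − 2).
    """
    if n_frames < 4:
        raise ValueError("need at least 4 frames")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    f_crit = sps.f.ppf(1 - alpha, 1, n_frames - 2)
    return float(f_crit / (f_crit + n_frames - 2))


@dataclass(frozen=True)
class ThresholdSpec:
    """Significance level, run length and the derived R² threshold."""

    alpha: float = 0.05
    n_frames: int = 134
    r2_crit: float | None = None

    def __post_init__(self) -> None:
        if self.r2_crit is None:
            object.__setattr__(self, "r2_crit", critical_r2(self.n_frames, self.alpha))
        if not 0 < self.r2_crit < 1:
            raise ValueError("r2_crit must be in (0, 1)")


@dataclass
class RegionSummary:
    """Per-mask summary over threshold-passing voxels.

    ``mean_r2_passing`` is in percent variance explained (0–100);
    ``mean_beta_all`` (all in-mask voxels, no threshold) is kept for
    transparency. ``mean_delay_passing`` is None for analyses without a
    delay map.
    """

    mask_name: str
    n_voxels: int
    n_passing: int
    pct_passing: float
    mean_r2_passing: float
    mean_beta_passing: float
    mean_delay_passing: float | None
    mean_beta_all: float


def threshold_by_r2(
    result: CvrResult, mask: np.ndarray, spec: ThresholdSpec
) -> np.ndarray:
    """Voxels of ``mask`` whose R² exceeds the chance threshold."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != result.r2.shape:
        raise GridMismatchError("mask and R² map must share one grid")
    return mask & (result.r2 > spec.r2_crit)


def summarize_mask(
    result: CvrResult,
    mask: np.ndarray,
    spec: ThresholdSpec,
    name: str = "",
) -> RegionSummary:
    """Summarize one mask: % voxels passing and means over passing voxels."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn(f"mask '{name}' is empty", EmptyMaskWarning)
        return RegionSummary(name, 0, 0, 0.0, math.nan, math.nan, None, math.nan)
    passing = threshold_by_r2(result, mask, spec)
    np_ = int(passing.sum())
    if np_ == 0:
        mean_r2 = mean_beta = math.nan
        mean_delay = math.nan if result.delay is not None else None
    else:
        mean_r2 = float(result.r2[passing].mean()) * 100.0
        mean_beta = float(result.beta[passing].mean())
        mean_delay = (
            float(result.delay[passing].mean()) if result.delay is not None else None
        )
    return RegionSummary(
        mask_name=name,
        n_voxels=n,
        n_passing=np_,
        pct_passing=100.0 * np_ / n,
        mean_r2_passing=mean_r2,
        mean_beta_passing=mean_beta,
        mean_delay_passing=mean_delay,
        mean_beta_all=float(result.beta[mask].mean()),
    )


def delay_difference(left: RegionSummary, right_homologue: RegionSummary) -> float:
    """Mean delay in a left mask minus that of its right homologue (s).

    Zero means no interhemispheric delay difference. Raises for analyses
    without a delay map (RHsig).
    """
    if left.mean_delay_passing is None or right_homologue.mean_delay_passing is None:
        raise ValueError("delay difference needs delay-carrying summaries (VoxOpt)")
    return left.mean_delay_passing - right_homologue.mean_delay_passing


@dataclass
class CompareResult:
    """Outcome of a t-test between groups/sessions of per-subject values."""

    t: float
    p: float
    kind: str
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    degenerate: bool = False


def compare(
    a,
    b=None,
    *,
    paired: bool = False,
) -> CompareResult:
    """t-test of per-subject summary values.

    One-sample vs 0 when ``b`` is None (delay-difference testing), Student
    paired when ``paired``, else Welch unpaired. Two-sided p throughout.
    Identical paired samples give (t=0, p=1); a zero-variance nonzero paired
    difference is flagged degenerate with t = ±inf.
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 values per group")
    if b is None:
        t, p = sps.ttest_1samp(a, 0.0)
        return CompareResult(
            float(t), float(p), "one-sample", (a.size,),
            (float(a.mean()),), (float(a.std(ddof=1)),),
        )
    b = np.asarray(b, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 values per group")
    stats_pair = (
        (float(a.mean()), float(b.mean())),
        (float(a.std(ddof=1)), float(b.std(ddof=1))),
    )
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal, matched lengths")
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return CompareResult(0.0, 1.0, "paired", (a.size, b.size),
                                     *stats_pair)
            return CompareResult(
                math.copysign(math.inf, diff[0]), 0.0, "paired",
                (a.size, b.size), *stats_pair, degenerate=True,
            )
        t, p = sps.ttest_rel(a, b)
        return CompareResult(float(t), float(p), "paired", (a.size, b.size),
                             *stats_pair)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return CompareResult(float(t), float(p), "welch", (a.size, b.size), *stats_pair)
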