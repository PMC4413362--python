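# Methods

This note documents the models, numerical choices and limitations behind
`cvrbh`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
reproduce.

## End-tidal CO₂ regressor

A capnograph trace (time in s, pCO₂ in mmHg, ≈200 Hz) is reduced to one
end-tidal value per breath, the expiratory maximum. Detection uses a
moving-average smoothing of 0.25 s, prominence-based peak picking
(minimum prominence 1 mmHg) with a minimum inter-breath interval of 1.5 s
(closer candidates are merged into one breath), and then reads the raw
local maximum within ±0.1 s of the smoothed peak so that noiseless
waveform maxima are recovered exactly. The smoothing is edge-padded with
edge values; zero padding would fabricate maxima at the recording
boundaries. All four parameters are exposed; the defaults were chosen for
robustness on noisy nasal-cannula capnography and are not sacred.

Within each breath-hold window the end-tidal trace is undefined; the
pipeline discards any detection strictly inside a hold and interpolates
linearly between the final pre-hold breath and the first post-hold breath
(the "quick exhalation", which carries the CO₂ accumulated during apnea).
Between ordinary breaths interpolation is also linear — nearest-breath
steps were the alternative; linear was chosen because end-tidal CO₂
tracks arterial CO₂, which evolves continuously. The interpolated trace
lives on a uniform 0.1 s grid, the same resolution as the delay search.

Convolution uses the canonical double-gamma HRF (peak at 6 s, undershoot
at 16 s, unit dispersions, undershoot ratio 6, 32 s support) normalized to
unit area, so a sustained step of A mmHg converges to exactly A mmHg:
the regressor amplitude keeps physical units and the GLM slope is CVR in
%BOLD per mmHg. The input is left-padded with its first value, making the
convolution causal and exactly constant-preserving. Frame sampling takes
the value at each frame midpoint, `t0 + (k + 0.5)·TR`, with the shift
applied at 0.1 s resolution before TR sampling and constant padding at the
series boundaries; slice-timing offsets are ignored.

## BOLD preparation

Each in-mask voxel is divided by its temporal mean and scaled to 100
(voxels with non-positive mean are dropped from the mask with a warning),
then its least-squares linear drift is removed on a centered time axis,
which preserves the 100 baseline and makes the operation idempotent. The
global signal is the plain in-mask mean per frame, computed after
detrending. No spatial smoothing is applied anywhere, so CVR cannot bleed
across the infarct boundary; a test asserts that a single-voxel pattern
survives the module untouched. Head motion is summarized as frame-wise
displacement: the sum of absolute frame-to-frame translations plus
rotations converted to arc length on a 50 mm sphere, with the mean taken
over frames 2..N.

## CVR estimators

All fits are one-regressor GLMs (intercept + model), solved in closed form
and vectorized over voxels; R² is the squared correlation. The delay grid
is −15 … +15 s in 0.1 s steps (exact zero is always on the grid), ties in
R² are broken toward the smallest absolute delay, and an optimum on the
search boundary raises a warning. The voxel-wise search runs over offsets
relative to the globally optimized delay, so absolute voxel delays may
reach the global optimum ±15 s; both absolute and relative delays are
stored. Negative betas are retained — CVR can genuinely invert in
pathology — and all thresholding is on R² only, sign-blind.

One deliberate choice: the shifted regressors are linearly detrended
before fitting (`detrend_design=True`), i.e. the design receives the same
temporal preprocessing as the data. Fitting detrended data on a
non-detrended regressor attenuates every beta by the squared
regressor–time correlation (≈1.4 % under the default paradigm, driven by
the convolution onset transient); detrending the design removes this bias
exactly without changing the regressor's mmHg scale. The GLM itself stays
intercept + regressor.

RHsig regresses each voxel on the mean %BOLD series of a reference mask
(the entire contralesional hemisphere, taken literally — no thresholding
of the reference voxels) with the 100 baseline removed, and scales betas
×100: a voxel identical to the reference series scores exactly 100 %.
RHsig has no delay model; that is a property of the method, not an
omission.

## Mask algebra

The peri-infarct shell is all voxels within 10 mm (Euclidean,
center-to-center, in world mm via a distance transform that honours
anisotropic voxels) of the lesion, minus the lesion. Dilation in
millimetres rather than voxels was chosen because acquisition grids are
anisotropic (3.5×3.5×3 mm here). The hemisphere split and the homologue
reflection are defined by the mid-sagittal plane (x = 0) of a
left/right-symmetric standard space reached through a 4×4 voxel-to-standard
affine; voxels exactly on the plane belong to neither hemisphere. The
reflection composes subject→standard, x-sign flip, and standard→subject
into a single nearest-neighbour resample — one rounding step instead of
two — and reduces to an exact x-index reversal (an involution) when the
grid is already midline-symmetric. Lesion and shell are clipped to
left-hemisphere brain so that lesion ∪ shell ∪ healthy exactly partitions
it; an optional small right-hemisphere lesion mask can be subtracted from
the right-side masks.

## Regional statistics

The R² threshold is the P = 0.05 point of the null distribution of R² for
a one-regressor GLM: `R²_crit = F_crit(1, N−2) / (F_crit + N − 2)`,
computed from the actual run length rather than hard-coded (N = 134 gives
0.0288). Summaries report the percentage of voxels passing and the means
of R² (as percent variance), beta and delay over passing voxels only; the
unthresholded mean beta is also kept for transparency. Delay differences
are left-region mean minus right-homologue mean, so 0 means no
interhemispheric difference. Paired and one-sample comparisons use
Student's t; unpaired comparisons use Welch's t (unequal variances — the
natural default for patient-vs-control contrasts); no multiple-comparison
correction is applied anywhere.

## Synthetic study

The generator's defaults are the study conditions, not tuning knobs.

*Capnograph*: raised-cosine breaths at 0.25 Hz between an inspiratory
level of 4 mmHg and an end-tidal peak of 40 mmHg; flat at the inspiratory
level during each 15 s hold (no airflow); the first post-hold breath peaks
at exactly 48 mmHg (8 mmHg boost — the boost magnitude is a generator
choice, exposed in config, as no canonical patient value exists), relaxing
back to baseline with a 12 s time constant; 10 s of recovery breathing is
appended after the final hold so its boost is observable; white sensor
noise of 0.2 mmHg.

*Phantom*: a midline-symmetric ellipsoidal brain on a 32×38×32 grid of
3.5×3.5×3 mm voxels (≈15 000 brain voxels) with a 14 mm-radius spherical
lesion centred at (−28, 4, 6) mm. Regional CVR truth is 0.29 / 0.21 /
0.19 %BOLD/mmHg for healthy / peri-infarct / lesion; right-hemisphere
mirror regions carry healthy values. Hemodynamic delays are a 4 s bulk
CO₂→brain transit (lung diffusion, blood transport and the capnograph
sampling line motivate a positive bulk delay; 4 s is a representative
choice) plus +1.2 s in the shell and +1.8 s in the lesion. The shell is
built through the same mask algebra the analysis uses, so feeding the
phantom's lesion back through `build_mask_set` reproduces every label
exactly.

*Forward model*: per-voxel delays are applied to the HRF-convolved CO₂
series at its native 0.1 s resolution, then
`y = B·(1 + [cvr·Δx + drift·(t−t̄) + shared + ε]/100)` with Δx the
regressor excursion about its mean, drift 0.01 %BOLD/frame, and white
voxel noise of 0.5 %BOLD. Signal terms are centred on the temporal mean so
%BOLD conversion inverts the model exactly, which is what makes noiseless
recovery an identity check: the pipeline then returns the regional truth
to machine precision and voxel delays to within one 0.1 s grid step.

The optional *shared* component is one series added to every brain voxel,
used to calibrate the global-signal fit to a patient-level quality
(R² ≈ 0.38): its sd is `sd(signal)·sqrt((1−R²)/R²)`. It is white Gaussian
residualized against {1, t, bulk-delay regressor} before scaling, so it is
stimulus-independent by construction — without that orthogonalization its
chance correlation with the regressor (sd ≈ N^(−1/2)) would inject a
seed-dependent common beta error of order ±10 % that reflects the
finite-sample draw, not the estimators. The shared component also couples
regional summaries within a session, as common physiology does in real
cohorts.

What the phantom does **not** emulate: respiratory mechanics and
within-breath capnogram shape variability, cardiac/respiratory
quasi-periodic fMRI noise, subject motion, spatial autocorrelation of
noise, partial-volume effects at mask boundaries, and poor task
compliance. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise model, not robustness to every
artefact of real acquisitions.

## Problem sizes and determinism

The voxel-wise grid search is computed as one matrix product per phantom
(voxels × delays), so the full ±15 s search on the default phantom takes
seconds; tests and the reproduction script use the default phantom with a
±3–5 s voxel window (the injected offsets are ≤ 1.8 s) and three seeds for
the noisy-recovery averages. The longitudinal null check uses 10 synthetic
subjects × 2 sessions on a reduced 20×24×20 grid with the patient-level
shared noise, so that the four regional tests share within-session
variance as they would in a real cohort. Every stochastic step takes an
explicit integer seed; a fixed seed yields bitwise-identical traces and
phantoms.

## Known limitations

* The end-tidal raw-max readout has a small positive bias under sensor
  noise (max over ~40 samples); it is common to baseline and boost breaths
  and largely cancels in the regressor excursion that drives CVR.
* Delay estimates at low SNR are selection-biased (the argmax of a noisy
  R² profile); regional delay differences cancel most of this, voxelwise
  delay maps at R² ≪ 0.1 should not be trusted.
* RHsig values are relative to the chosen reference mask and are biased
  toward it; they are not comparable across subjects in physical units.
* Registration to standard space is consumed, not estimated; mask
  reflection quality is bounded by the supplied affine.
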