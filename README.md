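# cvrbh — breath-hold cerebrovascular reactivity mapping for stroke fMRI

BOLD fMRI is routinely used to track recovery after stroke, but stroke is a
vascular disease: if cerebrovascular reactivity (CVR) — the BOLD response per
unit vasodilatory stimulus — is altered around the infarct, longitudinal
"activation" changes can be vascular artefacts rather than neural ones.
`cvrbh` implements a breath-hold CVR assessment pipeline for exactly this
situation: it turns a capnograph recording from a cyclic breath-hold task
(14 s natural breathing, 16 s paced breathing, 15 s end-expiration hold,
six cycles at TR = 2 s) into a quantitative end-tidal CO₂ regressor and maps
CVR in %BOLD per mmHg with explicit handling of regionally delayed
hemodynamics, which are common in peri-infarct tissue.

## The model

Each voxel's prepared %BOLD series `y_v(t)` is fit with a one-regressor GLM

    y_v(t) = β_v · x(t − τ) + c_v + ε_v(t)

where `x` is the end-tidal CO₂ trace (per-breath expiratory maxima, linear
interpolation across each hold between the last pre-hold breath and the
post-hold quick exhalation, then a scale-invariant convolution with the
canonical double-gamma HRF so the regressor keeps mmHg units). Three
estimators differ in how the delay `τ` is chosen:

* **GlobOpt** — one `τ` for the whole brain, found by exhaustive search
  (−15 … +15 s, 0.1 s steps) against the global BOLD signal. `β` is CVR in
  %BOLD/mmHg.
* **VoxOpt** — `τ` re-optimized per voxel on the same grid of offsets around
  the global optimum; the per-voxel delay map is itself an output. By
  construction every voxel's R² is at least its GlobOpt R².
* **RHsig** — no capnograph needed: the mean %BOLD series over the
  contralesional (right) hemisphere is the model, and `β` is expressed as a
  percentage of that reference amplitude (100 % = same amplitude).

Region analysis follows the stroke-mask family: the lesion, a 10 mm
peri-infarct shell (Euclidean dilation in world mm minus the lesion), the
remaining left-hemisphere "healthy" tissue, and their right-hemisphere
homologues obtained by reflecting about the mid-sagittal plane of a
symmetric standard space. Voxels only enter regional averages if their R²
exceeds the chance level for the run length — `R²_crit = F_crit /
(F_crit + N − 2)`, which is 0.0288 for the canonical 134-frame run at
P = 0.05 — and regions are compared with paired / Welch / one-sample
t-tests without multiple-comparison correction.

Because real stroke acquisitions cannot ship with the package, a synthetic
module generates the full study: capnograph traces with the hold-induced
8 mmHg end-tidal boost, and 4D stroke phantoms (32×38×32 voxels of
3.5×3.5×3 mm) with known regional CVR (0.29 / 0.21 / 0.19 %BOLD/mmHg for
healthy / peri-infarct / lesion), regional delays (+1.2 s shell, +1.8 s
lesion over a 4 s bulk transit delay), drift and noise. Every pipeline
stage is validated by parameter recovery against this ground truth.

## Worked example

```python
import numpy as np
from cvrbh import run_phantom_study, critical_r2

study = run_phantom_study(seed=7, noise_sd=0.5, target_global_r2=0.38)
s = study.summaries["voxopt"]
print(f"R2 threshold (134 frames): {critical_r2(134):.4f}")
print(f"global CO2->BOLD delay:    {study.voxopt.global_delay:+.1f} s "
      f"(fit R2 {study.global_fit_r2:.2f})")
for mask in ("l_healthy", "l_peri_infarct", "l_lesion"):
    print(f"{mask:15s} CVR {s[mask].mean_beta_passing:.3f} %BOLD/mmHg  "
          f"({s[mask].pct_passing:.0f}% voxels pass)")
print(f"peri-infarct delay vs homologue: "
      f"{study.delay_diff('peri_infarct'):+.2f} s")
```

prints

```
R2 threshold (134 frames): 0.0288
global CO2->BOLD delay:    +3.9 s (fit R2 0.38)
l_healthy       CVR 0.291 %BOLD/mmHg  (100% voxels pass)
l_peri_infarct  CVR 0.210 %BOLD/mmHg  (100% voxels pass)
l_lesion        CVR 0.190 %BOLD/mmHg  (100% voxels pass)
peri-infarct delay vs homologue: +1.31 s
```

i.e. with the global fit calibrated to the patient-level quality
(R² ≈ 0.38), the voxel-delay-optimized analysis recovers the injected
regional CVR (0.29 / 0.21 / 0.19) to a few percent and detects the extra
~1.2 s hemodynamic lag of the peri-infarct shell relative to its mirror
region.

A `cvr-bh` command-line tool exposes the same steps on files
(`simulate`, `regressor`, `prep`, `fit`, `masks`, `summarize`, `compare`);
see `cvr-bh --help`.

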