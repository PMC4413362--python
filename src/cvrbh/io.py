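"""Readers and writers for the on-disk formats the pipeline consumes.

Capnograph traces and motion parameters travel as TSV, the paradigm as YAML,
images and masks as NIfTI-1, affines as 4×4 whitespace text matrices (the
FLIRT .mat dialect).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import BoldRun, MotionParams
from .capnometry import CapnoTrace, Co2Regressor
from .paradigm import Paradigm

__all__ = [
    "read_capno_tsv",
    "write_regressor_tsv",
    "read_paradigm_yaml",
    "read_motion_tsv",
    "read_affine_mat",
    "load_bold",
    "save_bold",
    "load_mask",
    "save_mask",
    "save_map",
    "write_json",
]


def read_capno_tsv(path: str | Path, mmhg_factor: float = 1.0) -> CapnoTrace:
    """Read a capnograph TSV with columns ``time_s`` and ``pco2_mmhg``.

    ``mmhg_factor`` converts non-mmHg recordings on read (e.g. %CO2 to mmHg
    at barometric pressure: factor (P_bar − 47)/100).
    """
    df = pd.read_csv(path, sep="\t")
    time = df["time_s"].to_numpy(dtype=float)
    pco2 = df["pco2_mmhg"].to_numpy(dtype=float) * mmhg_factor
    fs = 1.0 / float(np.median(np.diff(time)))
    return CapnoTrace(time=time, pco2=pco2, sampling_rate=fs)


def write_regressor_tsv(path: str | Path, reg: Co2Regressor) -> None:
    pd.DataFrame(
        {"frame": np.arange(reg.n_frames), "co2_mmhg": reg.values}
    ).to_csv(path, sep="\t", index=False)


def read_paradigm_yaml(path: str | Path) -> Paradigm:
    """Read cycle timings (natural_s, paced_s, hold_s, n_cycles, tr) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return Paradigm(**cfg)


def read_motion_tsv(path: str | Path) -> MotionParams:
    """6-column TSV: tx, ty, tz (mm), rx, ry, rz (radians); no header required."""
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return MotionParams(translations=arr[:, :3], rotations=arr[:, 3:])


def read_affine_mat(path: str | Path) -> np.ndarray:
    """4×4 whitespace-separated affine (FLIRT .mat dialect)."""
    aff = np.loadtxt(path)
    if aff.shape != (4, 4):
        raise ValueError("affine file must be a 4x4 matrix")
    return aff


def load_bold(path: str | Path, brain_mask: np.ndarray | None = None,
              tr: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(np.asarray(img.dataobj, dtype=float), tr=tr,
                   affine=img.affine, brain_mask=brain_mask)


def save_bold(path: str | Path, run: BoldRun) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (run.tr,))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0.5


def save_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def save_map(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
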