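"""Stroke lesion mask algebra: peri-infarct shell, hemisphere split, and
left/right homologue reflection.

The mask family mirrors the standard stroke-CVR analysis: the (left-
lateralized) lesion, a 10 mm peri-infarct shell around it, the remaining
"healthy" left-hemisphere tissue, whole-hemisphere masks, and the mirror
images of the left regions in the contralesional right hemisphere.

Geometry is handled in world millimetres (anisotropic voxels honoured) and
the left/right reflection is taken about the x = 0 mid-sagittal plane of a
left/right-symmetric standard space reached through a user-supplied
voxel-to-standard affine; masks are resampled nearest-neighbour so they stay
binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskWarning, GridMismatchError

__all__ = [
    "MaskSet",
    "make_peri_infarct",
    "make_healthy",
    "flip_homologous",
    "hemisphere_split",
    "centered_vox2std",
    "build_mask_set",
]


@dataclass
class MaskSet:
    """The eight region masks on the subject grid, plus the standard-space affine."""

    l_lesion: np.ndarray
    l_peri_infarct: np.ndarray
    l_healthy: np.ndarray
    l_hemi: np.ndarray
    r_hemi: np.ndarray
    r_lesion: np.ndarray
    r_peri_infarct: np.ndarray
    r_healthy: np.ndarray
    affine_to_std: np.ndarray | None = None

    def named(self) -> dict[str, np.ndarray]:
        return {
            "l_lesion": self.l_lesion,
            "l_peri_infarct": self.l_peri_infarct,
            "l_healthy": self.l_healthy,
            "l_hemi": self.l_hemi,
            "r_hemi": self.r_hemi,
            "r_lesion": self.r_lesion,
            "r_peri_infarct": self.r_peri_infarct,
            "r_healthy": self.r_healthy,
        }


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Physical voxel edge lengths in mm: column norms of the 3x3 block."""
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


def centered_vox2std(shape, voxel_size_mm) -> np.ndarray:
    """Voxel-to-standard affine placing the grid centre at the origin.

    On this affine the mid-sagittal plane (standard x = 0) is the grid's x
    mid-plane, so left/right reflection is an exact index reversal for
    even-sized grids.
    """
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size_mm, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -(shape - 1) / 2 * vs
    return aff


def make_peri_infarct(
    lesion: np.ndarray,
    affine: np.ndarray | None = None,
    radius_mm: float = 10.0,
) -> np.ndarray:
    """Dilate the lesion by ``radius_mm`` in world mm, then remove the lesion.

    A voxel belongs to the shell when its centre lies within ``radius_mm``
    (Euclidean, mm) of the nearest lesion-voxel centre. Computed with a
    distance transform using the physical voxel sizes, so anisotropic grids
    are handled correctly.
    """
    lesion = np.asarray(lesion, dtype=bool)
    if not np.any(lesion):
        warnings.warn("empty lesion: peri-infarct shell is empty", EmptyMaskWarning)
        return np.zeros_like(lesion)
    sampling = _voxel_sizes(affine) if affine is not None else np.ones(3)
    dist = ndimage.distance_transform_edt(~lesion, sampling=sampling)
    return (dist <= radius_mm) & ~lesion


def make_healthy(
    hemi: np.ndarray,
    lesion: np.ndarray,
    peri: np.ndarray,
    brain: np.ndarray,
) -> np.ndarray:
    """Hemisphere voxels inside the brain but outside lesion and shell."""
    arrs = [np.asarray(a, dtype=bool) for a in (hemi, lesion, peri, brain)]
    if len({a.shape for a in arrs}) != 1:
        raise GridMismatchError("all masks must share one voxel grid")
    hemi, lesion, peri, brain = arrs
    healthy = hemi & brain & ~lesion & ~peri
    if not np.any(healthy):
        warnings.warn("healthy mask is empty", EmptyMaskWarning)
    return healthy


def flip_homologous(
    mask: np.ndarray, affine_to_std: np.ndarray | None = None
) -> np.ndarray:
    """Reflect a mask about the standard-space mid-sagittal plane.

    With ``affine_to_std=None`` the grid is assumed already mid-plane
    symmetric along its first axis and the flip is an exact x-index reversal
    (an involution). Otherwise the subject-voxel → standard → x-sign-flip →
    subject-voxel map is composed into a single nearest-neighbour resample.
    """
    mask = np.asarray(mask, dtype=bool)
    if affine_to_std is None:
        return mask[::-1].copy()
    A = np.asarray(affine_to_std, dtype=float)
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine_to_std must be invertible")
    R = np.diag([-1.0, 1.0, 1.0, 1.0])
    M = np.linalg.inv(A) @ R @ A  # output voxel -> source voxel
    out = ndimage.affine_transform(
        mask.astype(np.float32), M[:3, :3], offset=M[:3, 3], order=0,
        mode="constant", cval=0.0,
    )
    return out > 0.5


def hemisphere_split(
    brain: np.ndarray, affine_to_std: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split the brain at the mid-sagittal plane.

    Standard-space x < 0 is left, x > 0 right; voxels exactly on the plane
    belong to neither. ``None`` means the grid mid-plane along axis 0.
    """
    brain = np.asarray(brain, dtype=bool)
    nx, ny, nz = brain.shape
    ii = np.arange(nx, dtype=float)
    if affine_to_std is None:
        x_std = (ii - (nx - 1) / 2)[:, None, None] * np.ones((1, ny, nz))
    else:
        A = np.asarray(affine_to_std, dtype=float)
        jj = np.arange(ny, dtype=float)
        kk = np.arange(nz, dtype=float)
        x_std = (
            A[0, 0] * ii[:, None, None]
            + A[0, 1] * jj[None, :, None]
            + A[0, 2] * kk[None, None, :]
            + A[0, 3]
        )
    eps = 1e-9
    return brain & (x_std < -eps), brain & (x_std > eps)


def build_mask_set(
    brain: np.ndarray,
    lesion: np.ndarray,
    affine: np.ndarray | None = None,
    affine_to_std: np.ndarray | None = None,
    radius_mm: float = 10.0,
    right_lesion: np.ndarray | None = None,
) -> MaskSet:
    """Construct the full mask family from a brain mask and a lesion mask.

    ``affine`` gives physical voxel sizes for the dilation; ``affine_to_std``
    defines the mid-sagittal plane and the homologue reflection. The left
    lesion/shell are clipped to left-hemisphere brain so that lesion, shell
    and healthy tissue exactly partition ``l_hemi ∩ brain``; right-hemisphere
    homologues are the reflections of the left regions. An optional
    ``right_lesion`` (small additional right-hemisphere infarct) is removed
    from the right-hemisphere masks.
    """
    brain = np.asarray(brain, dtype=bool)
    lesion = np.asarray(lesion, dtype=bool)
    if brain.shape != lesion.shape:
        raise GridMismatchError("brain and lesion masks must share one grid")
    l_hemi, r_hemi = hemisphere_split(brain, affine_to_std)
    if np.any(lesion & r_hemi):
        warnings.warn(
            "lesion crosses the midline; right-hemisphere part ignored in "
            "the left-lesion mask",
            EmptyMaskWarning,
        )
    l_lesion = lesion & l_hemi
    peri = make_peri_infarct(l_lesion, affine, radius_mm) if np.any(l_lesion) \
        else np.zeros_like(brain)
    l_peri = peri & l_hemi & brain
    l_healthy = make_healthy(l_hemi, l_lesion, l_peri, brain)

    r_lesion = flip_homologous(l_lesion, affine_to_std) & r_hemi & brain
    r_peri = flip_homologous(l_peri, affine_to_std) & r_hemi & brain & ~r_lesion
    if right_lesion is not None:
        extra = np.asarray(right_lesion, dtype=bool)
        r_hemi = r_hemi & ~extra
        r_lesion = r_lesion & ~extra
        r_peri = r_peri & ~extra
    r_healthy = r_hemi & brain & ~r_lesion & ~r_peri

    return MaskSet(
        l_lesion=l_lesion, l_peri_infarct=l_peri, l_healthy=l_healthy,
        l_hemi=l_hemi, r_hemi=r_hemi, r_lesion=r_lesion,
        r_peri_infarct=r_peri, r_healthy=r_healthy, affine_to_std=affine_to_std,
    )
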