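"""Shared volumetric containers and grid definitions.

A :class:`BoldImage` is a 4D BOLD series together with the grid metadata
(affine to MNI millimetres, TR) required by every downstream stage.  NIfTI
round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Full-brain MNI bounding box spanned by the standard 61 x 73 x 61 grid (mm).
MNI_BOUNDS = np.array([[-90.0, 90.0], [-126.0, 90.0], [-72.0, 108.0]])


def mni_3mm_grid() -> tuple[tuple[int, int, int], np.ndarray]:
    """Standard MNI-space 3 mm isotropic grid (61 x 73 x 61) and its affine."""
    affine = np.array(
        [
            [3.0, 0.0, 0.0, -90.0],
            [0.0, 3.0, 0.0, -126.0],
            [0.0, 0.0, 3.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return (61, 73, 61), affine


def compact_grid(shape: tuple[int, int, int], voxel_size_mm: float = 3.0) -> np.ndarray:
    """Affine for a miniature grid used at fixture scale.

    The grid keeps the requested isotropic voxel size and is centred on the
    MNI origin; coordinates of interest must be remapped into its (small)
    field of view with :func:`remap_mni`.
    """
    shape = np.asarray(shape, dtype=float)
    origin = -voxel_size_mm * (shape - 1) / 2.0
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = origin
    return affine


def remap_mni(xyz: tuple[float, float, float], shape: tuple[int, int, int],
              voxel_size_mm: float = 3.0) -> tuple[float, float, float]:
    """Proportionally remap a full-brain MNI coordinate into a compact grid.

    Each axis of the MNI bounding box is mapped linearly onto the compact
    grid's physical extent, preserving relative anatomical position.
    """
    xyz = np.asarray(xyz, dtype=float)
    half = voxel_size_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    lo, hi = MNI_BOUNDS[:, 0], MNI_BOUNDS[:, 1]
    frac = (xyz - lo) / (hi - lo)  # 0..1 along each MNI axis
    return tuple(-half + frac * 2 * half)


@dataclass
class BoldImage:
    """4D BOLD series with grid metadata.

    Parameters
    ----------
    data:
        Array of shape ``(X, Y, Z, T)``.
    affine:
        4x4 voxel-index -> MNI-mm affine; must be invertible.
    tr:
        Repetition time in seconds.
    mask:
        Boolean brain mask of shape ``(X, Y, Z)``; defaults to all-true.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match spatial shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> float:
        return float(np.abs(np.linalg.det(self.affine[:3, :3])) ** (1.0 / 3.0))

    def with_data(self, data: np.ndarray) -> "BoldImage":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def voxel_timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """In-mask voxel time series as a ``(T, V)`` array."""
        m = self.mask if mask is None else np.asarray(mask, dtype=bool)
        return self.data[m].T

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], float(self.tr)))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, tr: float | None = None,
             mask: np.ndarray | None = None) -> "BoldImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr_eff = float(tr) if tr is not None else float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_eff <= 0:
            raise ValueError("TR missing from header; pass tr explicitly")
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr_eff, mask)


def mm_to_voxel(affine: np.ndarray, xyz_mm: np.ndarray) -> np.ndarray:
    """Map MNI mm coordinates to (fractional) voxel indices."""
    inv = np.linalg.inv(affine)
    xyz_mm = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    hom = np.c_[xyz_mm, np.ones(len(xyz_mm))]
    return (hom @ inv.T)[:, :3]


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices to MNI mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    hom = np.c_[ijk, np.ones(len(ijk))]
    return (hom @ np.asarray(affine, dtype=float).T)[:, :3]
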