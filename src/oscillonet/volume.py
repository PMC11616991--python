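"""Volumetric images on an MNI-mm grid.

A :class:`VolumeImage` is a thin container around a 3-D array plus a
voxel-index -> MNI-mm affine, mirroring the NIfTI-1 model used by nibabel.
The affine is the single source of truth for coordinate conversions; voxel
indices are 0-based. Missing data is encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "mni_grid",
    "read_nifti",
    "write_nifti",
]


@dataclass
class VolumeImage:
    """3-D grid of values with a voxel->MNI-mm affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D values, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    # -- coordinate transforms -------------------------------------------
    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        arr = np.asarray(ijk, dtype=float)
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of MNI-mm points."""
        arr = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        out = np.atleast_2d(arr) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def contains_mm(self, xyz) -> bool:
        """Whether the point falls inside the grid bounding box."""
        v = np.atleast_2d(self.mm_to_voxel(xyz))
        lo = v >= -0.5
        hi = v <= np.asarray(self.shape) - 0.5
        return bool(np.all(lo & hi))

    # -- conversions ------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float64), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeImage":
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(values=data, affine=np.asarray(img.affine))

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.values.copy(), self.affine.copy())

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def mni_grid(
    shape: tuple[int, int, int] = (91, 109, 91),
    voxel_mm: float = 2.0,
    origin_mm: tuple[float, float, float] = (90.0, -126.0, -72.0),
) -> VolumeImage:
    """Empty template on the standard 2 mm MNI-like grid (91 x 109 x 91).

    The affine follows the common radiological convention with x decreasing
    along the first axis (RAS- affine of the MNI152 2 mm template).
    """
    affine = np.array(
        [
            [-voxel_mm, 0.0, 0.0, origin_mm[0]],
            [0.0, voxel_mm, 0.0, origin_mm[1]],
            [0.0, 0.0, voxel_mm, origin_mm[2]],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return VolumeImage(np.zeros(shape), affine)


def read_nifti(path) -> VolumeImage:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    return VolumeImage.from_nifti(img)


def write_nifti(vol: VolumeImage, path) -> None:
    nib.save(vol.to_nifti(), str(path))
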