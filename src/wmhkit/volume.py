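"""Lightweight 3-D image container with NIfTI-1 round-tripping.

Every stage of the pipeline (phantom simulation, WMH detection, grey-matter
morphometry) works on :class:`ImageVolume` objects: a scalar voxel grid plus
the 4x4 voxel-to-world affine.  World coordinates are always in millimetres;
voxel indices are 0-based grid indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "ImageVolume",
    "read_volume",
    "write_volume",
]


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid with its voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Voxel values: FLAIR intensities, GM densities, or {0,1} masks.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm mapping (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires 3-D data, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        out = hom @ self.affine.T
        return np.squeeze(out[:, :3])

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid with different voxel values."""
        return ImageVolume(data, self.affine.copy())

    # -- I/O --------------------------------------------------------------
    @classmethod
    def load(cls, path) -> "ImageVolume":
        return read_volume(path)

    def save(self, path) -> None:
        write_volume(self, path)


def check_same_grid(reference: ImageVolume, **named: ImageVolume) -> None:
    """Raise :class:`GridMismatchError` naming the first mismatching input."""
    for name, vol in named.items():
        if not reference.same_grid(vol):
            raise GridMismatchError(
                f"input '{name}' does not share the reference grid "
                f"(shape {vol.shape} vs {reference.shape})"
            )


def read_volume(path) -> ImageVolume:
    """Read a single-frame 3-D NIfTI-1 volume (.nii or .nii.gz).

    Raises ``ValueError`` for 4-D files or non-finite affines.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single 3-D frame, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: non-finite or missing affine")
    return ImageVolume(np.asarray(data), np.asarray(affine, dtype=float))


def write_volume(vol: ImageVolume, path) -> None:
    """Write as NIfTI-1 preserving dtype, data and affine bit-exactly."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.set_data_dtype(vol.data.dtype)
    # identity scaling so the round trip is bit-exact
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))
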