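"""Minimal 3D volume container with voxel spacing and NIfTI round-trip.

A :class:`Volume` is a plain 3D array plus physical metadata: voxel spacing in
millimetres and a world origin. World coordinates follow ``index * spacing +
origin`` on an axis-aligned grid; oblique affines are out of scope. Voxel
indexing is 0-based and boxes are half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A single-channel 3D image on a regular grid.

    Parameters
    ----------
    data:
        3D array of intensities or labels.
    spacing_mm:
        Voxel spacing along each axis, in mm; strictly positive.
    origin:
        World coordinate of voxel (0, 0, 0), in mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing_mm) != 3 or len(self.origin) != 3:
            raise ValueError("spacing_mm and origin must have 3 components")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        """Return a copy, optionally substituting the data array."""
        d = self.data.copy() if data is None else np.asarray(data)
        return Volume(d, self.spacing_mm, self.origin)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(np.asanyarray(self.data), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        return cls(data, spacing, origin)
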