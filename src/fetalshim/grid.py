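"""Voxel-grid geometry shared by every image-like object.

All images in the package live on a regular 3-D grid indexed ``(x, y, z)``,
0-based, with physical coordinates in millimetres relative to magnet
isocenter.  Masks and maps that are combined must share geometry bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


class GeometryError(ValueError):
    """Raised when two image objects do not share grid geometry."""


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: shape, voxel size (mm) and origin (mm).

    ``origin`` is the physical position of the center of voxel (0, 0, 0);
    the grid axes are assumed aligned with the magnet axes (z along B0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, shape, spacing) -> "Grid":
        """Grid whose physical center coincides with isocenter."""
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(tuple(shape), tuple(spacing), origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def coords(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices, shape (N, 3)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij")

    def matches(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def require_match(self, other: "Grid", what: str = "images") -> None:
        if not self.matches(other):
            raise GeometryError(
                f"{what} do not share grid geometry: {self} vs {other}"
            )


def mask_index(mask: np.ndarray) -> np.ndarray:
    """Indices of True voxels in deterministic order (x fastest, then y, z)."""
    idx = np.argwhere(mask)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))
    return idx[order]


def save_nifti(data: np.ndarray, grid: Grid, path: str | Path, descrip: str = "") -> None:
    """Write an array to NIfTI-1 with the grid's affine; complex data is split
    into a 4th dimension (real, imag)."""
    arr = np.asarray(data)
    if np.iscomplexobj(arr):
        arr = np.stack([arr.real, arr.imag], axis=-1)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr.astype(np.float32) if arr.dtype != np.uint8 else arr,
                          grid.affine)
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path: str | Path, complex_pair: bool = False):
    """Read a NIfTI volume, returning (array, Grid).

    With ``complex_pair=True`` a 4-D volume whose last axis has length 2 is
    reassembled into a complex array (the convention used by save_nifti).
    """
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    if complex_pair:
        if arr.ndim != 4 or arr.shape[-1] != 2:
            raise ValueError("expected a 4-D (real, imag) pair volume")
        arr = arr[..., 0] + 1j * arr[..., 1]
    grid = Grid(arr.shape[:3], spacing, origin)
    return arr, grid
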