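"""3D scalar volumes on a regular grid.

The :class:`Volume` is the carrier for every image in the pipeline (MRC,
PPI, PEI, HYDROPS, HYDROPS-Mi2, masks, vote maps).  Axes are indexed
(0, 1, 2), 0-based; ``voxel_size`` is in mm per axis and ``origin`` is the
world (mm) coordinate of the corner of voxel (0, 0, 0).  World coordinates
of a voxel center are ``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "GridMismatchError", "load_nifti", "save_nifti"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class Volume:
    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in mm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid carrying ``data``."""
        if data.shape != self.data.shape:
            raise GridMismatchError(
                f"data shape {data.shape} does not match grid shape {self.data.shape}"
            )
        return replace(self, data=data)

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if self.shape != other.shape:
            raise GridMismatchError(f"{what}: shape differs ({self.shape} vs {other.shape})")
        if not np.allclose(self.voxel_size, other.voxel_size, atol=1e-6):
            raise GridMismatchError(
                f"{what}: voxel size differs ({self.voxel_size} vs {other.voxel_size})"
            )
        if not np.allclose(self.origin, other.origin, atol=1e-6):
            raise GridMismatchError(f"{what}: origin differs ({self.origin} vs {other.origin})")


def _affine(vol: Volume) -> np.ndarray:
    """RAS affine mapping voxel indices to world mm (voxel-center convention)."""
    aff = np.diag(list(vol.voxel_size) + [1.0])
    aff[:3, 3] = np.asarray(vol.origin) + 0.5 * np.asarray(vol.voxel_size)
    return aff


def save_nifti(vol: Volume, path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(vol))
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def load_nifti(path) -> Volume:
    img = nib.load(str(path))
    aff = img.affine
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    origin = tuple(float(aff[i, 3] - 0.5 * voxel[i]) for i in range(3))
    return Volume(np.asarray(img.dataobj), voxel, origin)
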