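"""HYDROPS / HYDROPS-Mi2 image construction and preprocessing.

HYDROPS is the voxelwise subtraction PPI - PEI: perilymph (bright on PPI,
dark on PEI) comes out positive, endolymph negative.  HYDROPS-Mi2 is the
product of HYDROPS with the MRC cisternography image, which suppresses the
(MRC-dark) background and boosts contrast-to-noise inside the fluid.

The preprocessing chain mirrors the volumetric pipeline: crop a cuboid
around the inner ears, convert to 8-bit, upsample by an integer factor with
quintic B-spline interpolation, and (for the MRC used in registration)
clip-and-stretch the histogram.  HYDROPS stays signed until after the Mi2
product; quantization to 8-bit happens on the Mi2 volume that feeds the
local-threshold ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "PreprocessConfig",
    "compute_hydrops",
    "compute_mi2",
    "crop_cuboid",
    "to_8bit",
    "rescale",
    "denoise_histogram",
    "preprocess_triplet",
]


@dataclass
class PreprocessConfig:
    crop_size_mm: tuple[float, float, float] = (30.0, 30.0, 52.0)
    rescale_factor: int = 2
    interpolation_order: int = 5  # quintic B-spline
    denoise_percentiles: tuple[float, float] = (0.5, 99.5)

    def __post_init__(self) -> None:
        if self.rescale_factor < 1:
            raise ValueError("rescale factor must be >= 1")
        lo, hi = self.denoise_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"invalid denoise percentiles {self.denoise_percentiles}")


def compute_hydrops(ppi: Volume, pei: Volume) -> Volume:
    """Voxelwise PPI - PEI, kept signed (no clipping)."""
    ppi.require_same_grid(pei, "PPI vs PEI")
    return ppi.with_data(ppi.data.astype(np.float64) - pei.data.astype(np.float64))


def compute_mi2(hydrops: Volume, mrc: Volume) -> Volume:
    """Voxelwise HYDROPS x MRC; MRC-dark background is suppressed toward 0."""
    hydrops.require_same_grid(mrc, "HYDROPS vs MRC")
    return hydrops.with_data(hydrops.data.astype(np.float64) * mrc.data.astype(np.float64))


def crop_cuboid(v: Volume, center_mm: tuple[float, float, float] | None = None,
                cfg: PreprocessConfig | None = None) -> Volume:
    """Crop a cuboid of physical size ``cfg.crop_size_mm`` centered at
    ``center_mm`` (defaults to the grid center).  Voxel size is unchanged;
    the output extent matches the request to within one voxel per axis."""
    cfg = cfg or PreprocessConfig()
    if center_mm is None:
        center_mm = tuple(0.5 * e + o for e, o in zip(v.extent_mm, v.origin))
    slices = []
    new_origin = []
    for ax in range(3):
        n = int(round(cfg.crop_size_mm[ax] / v.voxel_size[ax]))
        c_idx = (center_mm[ax] - v.origin[ax]) / v.voxel_size[ax]
        start = int(round(c_idx - n / 2.0))
        stop = start + n
        if start < 0 or stop > v.shape[ax]:
            clamped = (max(start, 0), min(stop, v.shape[ax]))
            raise ValueError(
                f"crop cuboid out of bounds along axis {ax}: requested voxels "
                f"[{start}, {stop}) of {v.shape[ax]}; nearest valid range {clamped}"
            )
        slices.append(slice(start, stop))
        new_origin.append(v.origin[ax] + start * v.voxel_size[ax])
    return Volume(v.data[tuple(slices)].copy(), v.voxel_size, tuple(new_origin))


def to_8bit(v: Volume) -> Volume:
    """Linear map of [min, max] to [0, 255], rounded half-to-even.

    A constant input maps to all-zero: with no dynamic range there is no
    contrast to preserve.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("to_8bit requires finite values")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return v.with_data(np.zeros_like(data, dtype=np.uint8))
    scaled = (data - lo) * (255.0 / (hi - lo))
    return v.with_data(np.rint(scaled).astype(np.uint8))


def rescale(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Upsample each axis by the integer factor with B-spline interpolation.

    Voxel size is divided by the factor so physical extent is preserved.
    """
    cfg = cfg or PreprocessConfig()
    f = int(cfg.rescale_factor)
    if f == 1:
        return v
    data = ndimage.zoom(
        np.asarray(v.data, dtype=np.float64),
        f,
        order=cfg.interpolation_order,
        mode="nearest",
        grid_mode=True,
    )
    voxel = tuple(s / f for s in v.voxel_size)
    return Volume(data, voxel, v.origin)


def denoise_histogram(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Histogram-based noise reduction: clip at the configured percentiles,
    then re-stretch linearly to the full 8-bit range."""
    cfg = cfg or PreprocessConfig()
    lo_p, hi_p = cfg.denoise_percentiles
    data = np.asarray(v.data, dtype=np.float64)
    lo = float(np.percentile(data, lo_p))
    hi = float(np.percentile(data, hi_p))
    if hi == lo:
        return v.with_data(data.copy())
    clipped = np.clip(data, lo, hi)
    stretched = (clipped - lo) * (255.0 / (hi - lo))
    return v.with_data(np.rint(stretched))


@dataclass
class PreprocessedSubject:
    """Processed volumes on the common (cropped, rescaled) analysis grid."""

    mrc: Volume  # 8-bit, denoised (registration/hull input)
    mi2: Volume  # 8-bit Mi2 (VOLT input)
    mi2_signed: Volume  # signed Mi2 before quantization


def preprocess_triplet(mrc: Volume, ppi: Volume, pei: Volume,
                       cfg: PreprocessConfig | None = None,
                       center_mm: tuple[float, float, float] | None = None) -> PreprocessedSubject:
    """Full preprocessing chain on a sequence triplet.

    Crop -> HYDROPS -> Mi2 -> rescale -> 8-bit; the MRC branch additionally
    receives the histogram clip-and-stretch used to stabilize registration.
    """
    cfg = cfg or PreprocessConfig()
    mrc_c = crop_cuboid(mrc, center_mm, cfg)
    ppi_c = crop_cuboid(ppi, center_mm, cfg)
    pei_c = crop_cuboid(pei, center_mm, cfg)
    hyd = compute_hydrops(ppi_c, pei_c)
    mi2 = compute_mi2(hyd, mrc_c)
    mi2_r = rescale(mi2, cfg)
    mrc_r = rescale(mrc_c, cfg)
    mrc_8 = denoise_histogram(to_8bit(mrc_r), cfg)
    mi2_8 = to_8bit(mi2_r)
    return PreprocessedSubject(mrc=mrc_8, mi2=mi2_8, mi2_signed=mi2_r)
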