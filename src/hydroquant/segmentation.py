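"""Atlas-guided segmentation of the total fluid space (TFS).

A probabilistic occupancy atlas is built from binarized labyrinth masks and
made side-independent by averaging with its left-right mirror.  The atlas
is registered to a subject's MRC volume with a 12-parameter affine
transform (3 translations, 3 rotations, 3 scales, 3 shears) found by a
multiresolution regular-step gradient descent on the mean-squared intensity
difference over randomly sampled voxels.  Within the registered atlas
region the MRC is thresholded (Otsu on the in-ROI histogram), the largest
connected component per side is kept and internal holes are filled,
yielding the binary hull of the TFS.  A dilated hull masks the HYDROPS-Mi2
image into the fusion volume on which the local-threshold ensemble runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .phantom import LabyrinthMask, substream
from .volume import Volume

__all__ = [
    "ProbabilisticAtlas",
    "AffineParams",
    "RegistrationConfig",
    "RegistrationError",
    "BinaryHull",
    "build_atlas",
    "register_affine",
    "resample_atlas",
    "extract_hull",
    "dilate_hull",
    "fuse",
    "FUSION_SENTINEL",
]

FUSION_SENTINEL = np.nan  # voxels outside the hull; excluded from all statistics


@dataclass
class ProbabilisticAtlas:
    occupancy: Volume  # values in [0, 1]
    side_independent: bool = True
    mirror_axis: int = 2

    def binarize(self, threshold: float = 0.5) -> Volume:
        return self.occupancy.with_data(self.occupancy.data >= threshold)

    def save(self, nifti_path, json_path=None) -> None:
        from .volume import save_nifti

        save_nifti(self.occupancy, nifti_path)
        if json_path is not None:
            meta = {"side_independent": self.side_independent, "mirror_axis": self.mirror_axis}
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def build_atlas(masks: list[LabyrinthMask], mirror_axis: int = 2) -> ProbabilisticAtlas:
    """Mean of binarized fluid masks, averaged with its left-right mirror."""
    if not masks:
        raise ValueError("build_atlas requires at least one mask")
    ref = masks[0]
    acc = np.zeros(ref.label.shape, dtype=np.float64)
    for m in masks:
        if m.label.shape != ref.label.shape:
            raise ValueError("all masks must share one grid")
        acc += (m.label > 0).astype(np.float64)
    occ = acc / len(masks)
    occ = 0.5 * (occ + np.flip(occ, axis=mirror_axis))
    vol = Volume(occ, ref.voxel_size, ref.origin)
    return ProbabilisticAtlas(vol, side_independent=True, mirror_axis=mirror_axis)


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------


@dataclass
class AffineParams:
    """12-DOF affine, moving (atlas) -> fixed (MRC) world coordinates.

    ``x_fixed = R @ Sh @ S @ (x_moving - center) + center + translation``
    with R = Rz Ry Rx (radians), Sh unit upper-triangular with the three
    shear entries, S = diag(scale), and ``center`` the physical center of
    the fixed volume (mm).
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale parameters must be positive, got {self.scale}")

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        Sh = np.array(
            [[1, self.shear[0], self.shear[1]], [0, 1, self.shear[2]], [0, 0, 1]],
            dtype=float,
        )
        return Rz @ Ry @ Rx @ Sh @ np.diag(self.scale)

    def apply(self, pts_moving: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return (self.matrix() @ (pts_moving - c).T).T + c + np.asarray(self.translation)

    def inverse_map(self, pts_fixed: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        inv = np.linalg.inv(self.matrix())
        return (inv @ (pts_fixed - c - np.asarray(self.translation)).T).T + c

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    @classmethod
    def from_vector(cls, v: np.ndarray, center) -> "AffineParams":
        return cls(
            tuple(v[0:3]), tuple(v[3:6]), tuple(v[6:9]), tuple(v[9:12]), tuple(center)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class RegistrationConfig:
    sampling_fraction: float = 0.5
    max_step_length: float = 0.5
    min_step_length: float = 0.005
    max_iterations: int = 100
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    max_samples: int = 50_000  # cap at the finest level
    lever_arm_mm: float = 20.0  # converts rotation/scale/shear units to mm steps
    atlas_threshold: float = 0.5
    seed: int = 0
    strict_convergence: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.max_step_length <= 0:
            raise ValueError("max step length must be > 0")


class RegistrationError(RuntimeError):
    def __init__(self, msg: str, params: AffineParams, metric: float):
        super().__init__(msg)
        self.params = params
        self.metric = metric


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _downsample(vol: Volume, f: int) -> Volume:
    if f == 1:
        return vol
    sm = ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float64), sigma=f / 2.0)
    data = sm[::f, ::f, ::f]
    voxel = tuple(v * f for v in vol.voxel_size)
    # kept voxel centers sit at the original positions of voxels 0, f, 2f, ...
    origin = tuple(o - 0.5 * v * (f - 1) for o, v in zip(vol.origin, vol.voxel_size))
    return Volume(data, voxel, origin)


def _world_of_indices(vol: Volume, idx: np.ndarray) -> np.ndarray:
    return np.asarray(vol.origin) + (idx + 0.5) * np.asarray(vol.voxel_size)


def _sample_moving(moving: Volume, pts_world: np.ndarray) -> np.ndarray:
    idx = (pts_world - np.asarray(moving.origin)) / np.asarray(moving.voxel_size) - 0.5
    return ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64), idx.T, order=1, mode="constant", cval=0.0
    )


def _center_of_mass_world(vol: Volume) -> np.ndarray:
    w = _normalize(vol.data)
    total = w.sum()
    if total == 0:
        return np.asarray(vol.origin) + 0.5 * np.asarray(vol.extent_mm)
    com_idx = np.array(ndimage.center_of_mass(w))
    return _world_of_indices(vol, com_idx)


def register_affine(
    atlas: ProbabilisticAtlas, mrc: Volume, cfg: RegistrationConfig | None = None
) -> AffineParams:
    """Fit the 12-DOF affine aligning the atlas occupancy to the MRC.

    Regular-step gradient descent (step bounded by ``max_step_length``,
    halved whenever the descent direction reverses or the cost rises) on the
    MSE between normalized intensities, evaluated on a random voxel sample
    of size ``sampling_fraction`` per resolution level.  Deterministic for a
    fixed config seed.  Initialization aligns intensity centers of mass.
    """
    cfg = cfg or RegistrationConfig()
    center = tuple(np.asarray(mrc.origin) + 0.5 * np.asarray(mrc.extent_mm))

    # initial translation from centers of mass
    t0 = _center_of_mass_world(mrc) - _center_of_mass_world(atlas.occupancy)
    params = np.zeros(12)
    params[0:3] = t0
    params[6:9] = 1.0

    rho = cfg.lever_arm_mm
    scales = np.array([1.0, 1.0, 1.0, rho, rho, rho, rho, rho, rho, rho, rho, rho])

    moving_levels = [_downsample(atlas.occupancy, f) for f in cfg.shrink_factors]
    fixed_levels = [_downsample(mrc, f) for f in cfg.shrink_factors]

    best_cost = np.inf
    converged = False
    for lvl, (fx, mv) in enumerate(zip(fixed_levels, moving_levels)):
        fx_norm = fx.with_data(_normalize(fx.data))
        mv_norm = mv.with_data(_normalize(mv.data))
        rng = substream(cfg.seed, "registration", str(lvl))
        n_vox = int(np.prod(fx.shape))
        n_samp = min(int(round(cfg.sampling_fraction * n_vox)), cfg.max_samples)
        n_samp = max(n_samp, 1)
        flat = rng.choice(n_vox, size=n_samp, replace=False)
        idx = np.column_stack(np.unravel_index(flat, fx.shape)).astype(np.float64)
        pts_fixed = _world_of_indices(fx, idx)
        target = fx_norm.data.ravel()[flat]

        def cost(q: np.ndarray) -> float:
            p = q / scales
            ap = AffineParams.from_vector(p, center)
            pts_m = ap.inverse_map(pts_fixed)
            pred = _sample_moving(mv_norm, pts_m)
            return float(np.mean((pred - target) ** 2))

        q = params * scales
        step = cfg.max_step_length
        prev_grad = None
        c0 = cost(q)
        best_cost = c0
        eps = 0.02
        for _ in range(cfg.max_iterations):
            grad = np.zeros(12)
            for k in range(12):
                dq = np.zeros(12)
                dq[k] = eps
                grad[k] = (cost(q + dq) - cost(q - dq)) / (2 * eps)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                converged = True
                break
            direction = -grad / gnorm
            q_new = q + step * direction
            c_new = cost(q_new)
            if c_new < best_cost:
                q = q_new
                best_cost = c_new
                if prev_grad is not None and float(np.dot(grad, prev_grad)) < 0:
                    step *= 0.5
                prev_grad = grad
            else:
                step *= 0.5
            if step < cfg.min_step_length:
                converged = True
                break
        params = q / scales

    result = AffineParams.from_vector(params, center)
    if not converged and cfg.strict_convergence:
        raise RegistrationError(
            f"registration did not converge within {cfg.max_iterations} iterations "
            f"(final metric {best_cost:.3g})",
            result,
            best_cost,
        )
    return result


def resample_atlas(
    atlas: ProbabilisticAtlas,
    params: AffineParams,
    fixed: Volume,
    threshold: float = 0.5,
) -> Volume:
    """Binarized atlas occupancy resampled onto the fixed grid."""
    idx = np.indices(fixed.shape).reshape(3, -1).T.astype(np.float64)
    pts_fixed = _world_of_indices(fixed, idx)
    pts_m = params.inverse_map(pts_fixed)
    occ = _sample_moving(atlas.occupancy, pts_m).reshape(fixed.shape)
    return fixed.with_data(occ >= threshold)


# ---------------------------------------------------------------------------
# hull extraction and fusion
# ---------------------------------------------------------------------------


@dataclass
class BinaryHull:
    mask: Volume  # boolean
    side: Volume | None = None  # optional {0 none, 1 left, 2 right}
    roi: Volume | None = field(default=None, repr=False)  # dilated atlas ROI

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask.data))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.mask.voxel_volume_mm3


def extract_hull(
    mrc: Volume,
    atlas_mask: Volume,
    lr_axis: int = 2,
    roi_dilation: int = 2,
) -> BinaryHull:
    """Threshold the MRC inside the registered atlas ROI into the TFS hull.

    Otsu's threshold on the in-ROI histogram separates bright fluid from
    dark bone/background; the largest connected component per side is kept
    and internal holes are filled.
    """
    mrc.require_same_grid(atlas_mask, "MRC vs atlas mask")
    roi = np.asarray(atlas_mask.data, dtype=bool)
    if roi_dilation > 0:
        roi = ndimage.binary_dilation(roi, structure=ball(roi_dilation))
    vals = np.asarray(mrc.data, dtype=np.float64)[roi]
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("no fluid signal in ROI")
    thr = threshold_otsu(vals)
    fg = (np.asarray(mrc.data, dtype=np.float64) > thr) & roi
    if not fg.any():
        raise ValueError("no fluid signal in ROI")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no fluid signal in ROI")
    centers = ndimage.center_of_mass(fg, labels, index=range(1, n + 1))
    sizes = ndimage.sum_labels(fg, labels, index=range(1, n + 1))
    mid = 0.5 * mrc.shape[lr_axis]
    best = {"left": (0, 0.0), "right": (0, 0.0)}  # label, size
    for lab, (c, s) in enumerate(zip(centers, sizes), start=1):
        side = "left" if c[lr_axis] < mid else "right"
        if s > best[side][1]:
            best[side] = (lab, s)
    hull = np.zeros(fg.shape, dtype=bool)
    side_vol = np.zeros(fg.shape, dtype=np.uint8)
    for code, side in ((1, "left"), (2, "right")):
        lab = best[side][0]
        if lab == 0:
            continue
        comp = ndimage.binary_fill_holes(labels == lab)
        hull |= comp
        side_vol[comp] = code
    return BinaryHull(
        mask=mrc.with_data(hull),
        side=mrc.with_data(side_vol),
        roi=mrc.with_data(roi),
    )


def dilate_hull(h: BinaryHull, radius_voxels: int) -> BinaryHull:
    """Morphological dilation with a Euclidean ball structuring element."""
    if radius_voxels < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_voxels == 0:
        return h
    grown = ndimage.binary_dilation(
        np.asarray(h.mask.data, dtype=bool), structure=ball(radius_voxels)
    )
    side = h.side
    if side is not None:
        # grow side labels by nearest-side assignment within the grown mask
        dist_l = ndimage.distance_transform_edt(side.data != 1)
        dist_r = ndimage.distance_transform_edt(side.data != 2)
        side_new = np.where(dist_l <= dist_r, 1, 2).astype(np.uint8)
        side_new[~grown] = 0
        side = side.with_data(side_new)
    return BinaryHull(mask=h.mask.with_data(grown), side=side, roi=h.roi)


def fuse(h: BinaryHull, mi2: Volume) -> Volume:
    """Mi2 intensities inside the hull; outside voxels carry the sentinel
    (NaN) and are excluded from every downstream statistic."""
    h.mask.require_same_grid(mi2, "hull vs Mi2")
    mask = np.asarray(h.mask.data, dtype=bool)
    if not mask.any():
        raise ValueError("hull is empty")
    data = np.asarray(mi2.data, dtype=np.float64).copy()
    data[~mask] = FUSION_SENTINEL
    return mi2.with_data(data)
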