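"""Synthetic inner-ear phantoms with known ground truth.

The phantom is a stylized two-compartment membranous labyrinth per side: a
cochlea modeled as a spiral tube and a vestibule modeled as an ellipsoid,
mirrored left/right about the mid-sagittal plane.  Within each compartment
an inner sub-region is labeled endolymph so that the endolymph/fluid volume
fraction equals a requested value; the rest of the compartment is
perilymph.  Semicircular canals are not modeled (they are excluded from
grading anyway).

Axis convention (all in mm, voxel-center world coordinates):

* axis 0 - anterior-posterior
* axis 1 - inferior-superior; grading slices stack along this axis
* axis 2 - left-right; the mirror axis (left ear at low indices)

The endolymph sub-region is constructed so that not only the volume
fraction but also the *area* fraction on every grading slice equals the
requested fraction (for the vestibule), which is what the semi-quantitative
grade measures.  This is achieved by ranking voxels by a normalized
in-slice radial coordinate and labeling the innermost quantile.

A cohort generator produces subjects of three clinical flavors (vestibular
migraine, Meniere's disease, and the overlap group) whose neurotologic
records are linked monotonically to the ground-truth endolymph ratio, so
rank correlations between imaging and function are recoverable by
construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = [
    "CochleaSpec",
    "VestibuleSpec",
    "IntensityModel",
    "PhantomSpec",
    "LabyrinthMask",
    "SequenceTriplet",
    "NeurotologyRecord",
    "SyntheticSubject",
    "EffectModel",
    "build_labyrinth",
    "simulate_sequences",
    "generate_cohort",
    "cohort_to_dataframe",
    "substream",
]

# label codes
BACKGROUND, PERILYMPH, ENDOLYMPH = 0, 1, 2
COMP_NONE, COMP_COCHLEA, COMP_VESTIBULE = 0, 1, 2
SIDE_NONE, SIDE_LEFT, SIDE_RIGHT = 0, 1, 2

SEQUENCES = ("mrc", "ppi", "pei")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named child random stream, reproducible independently of call order."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


@dataclass
class CochleaSpec:
    """Spiral-tube cochlea: an Archimedean spiral in the axial plane with a
    small helical rise, swept by a tube of radius ``tube_radius_mm``."""

    center_offset_mm: tuple[float, float, float] = (-3.6, 0.0, 0.0)
    base_radius_mm: float = 3.0
    turns: float = 2.25
    tube_radius_mm: float = 0.9
    rise_mm: float = 0.8
    endolymph_fraction: tuple[float, float] = (0.25, 0.25)  # (left, right)


@dataclass
class VestibuleSpec:
    center_offset_mm: tuple[float, float, float] = (3.2, 0.0, 0.0)
    semi_axes_mm: tuple[float, float, float] = (2.5, 3.0, 2.5)
    endolymph_fraction: tuple[float, float] = (0.35, 0.35)  # (left, right)


def _default_intensities() -> dict[str, dict[str, float]]:
    return {
        "background": {"mrc": 5.0, "ppi": 5.0, "pei": 5.0},
        "bone": {"mrc": 5.0, "ppi": 5.0, "pei": 5.0},
        "perilymph": {"mrc": 220.0, "ppi": 200.0, "pei": 60.0},
        "endolymph": {"mrc": 220.0, "ppi": 40.0, "pei": 180.0},
    }


@dataclass
class IntensityModel:
    """Mean intensity per tissue class per sequence, on an 8-bit scale.

    Perilymph is bright on PPI and dark on PEI; endolymph the opposite, so
    PPI - PEI is positive in perilymph and negative in endolymph, matching
    the dark-ELS / bright-PLS appearance of the subtraction images.
    """

    means: dict[str, dict[str, float]] = field(default_factory=_default_intensities)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"mrc": 5.0, "ppi": 5.0, "pei": 5.0}
    )


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (72, 72, 112)
    voxel_size_mm: float = 0.5
    ear_separation_mm: float = 26.0
    cochlea: CochleaSpec = field(default_factory=CochleaSpec)
    vestibule: VestibuleSpec = field(default_factory=VestibuleSpec)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, fr in (
            ("cochlea", self.cochlea.endolymph_fraction),
            ("vestibule", self.vestibule.endolymph_fraction),
        ):
            for f in fr:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{name} endolymph fraction {f} outside [0, 1]")
        if self.cochlea.tube_radius_mm <= 0 or self.cochlea.base_radius_mm <= 0:
            raise ValueError("cochlea radii must be positive")
        if any(a <= 0 for a in self.vestibule.semi_axes_mm):
            raise ValueError("vestibule semi-axes must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_mm for s in self.grid_shape)  # type: ignore[return-value]

    def ear_centers_mm(self) -> dict[str, np.ndarray]:
        c = 0.5 * np.asarray(self.extent_mm)
        half = 0.5 * self.ear_separation_mm
        return {
            "left": np.array([c[0], c[1], c[2] - half]),
            "right": np.array([c[0], c[1], c[2] + half]),
        }

    def compartment_volumes_mm3(self) -> dict[str, float]:
        """Analytic fluid volumes of one vestibule and one cochlea."""
        a, b, c = self.vestibule.semi_axes_mm
        v_vest = 4.0 / 3.0 * np.pi * a * b * c
        # spiral arc length of r(t)=r0*(1-0.75*t), t in [0,1], angle=2*pi*turns*t
        t = np.linspace(0.0, 1.0, 2001)
        pts = _spiral_points(self.cochlea, t)
        seg = np.diff(pts, axis=0)
        arc = float(np.sqrt((seg**2).sum(axis=1)).sum())
        v_coch = arc * np.pi * self.cochlea.tube_radius_mm**2
        return {"vestibule": v_vest, "cochlea": v_coch}

    def true_els_ratio(self, side: str) -> float:
        """Ground-truth whole-ear ELS/TFS ratio implied by the requested fractions."""
        i = 0 if side == "left" else 1
        v = self.compartment_volumes_mm3()
        els = (
            self.vestibule.endolymph_fraction[i] * v["vestibule"]
            + self.cochlea.endolymph_fraction[i] * v["cochlea"]
        )
        return els / (v["vestibule"] + v["cochlea"])


@dataclass
class LabyrinthMask:
    """Ground-truth voxel labels: tissue class, compartment, and side."""

    label: np.ndarray  # {0 background, 1 perilymph, 2 endolymph}
    compartment: np.ndarray  # {0 none, 1 cochlea, 2 vestibule}
    side: np.ndarray  # {0 none, 1 left, 2 right}
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def fluid(self) -> np.ndarray:
        return self.label > 0

    @property
    def endolymph(self) -> np.ndarray:
        return self.label == ENDOLYMPH

    def as_volume(self, which: str = "label") -> Volume:
        return Volume(getattr(self, which), self.voxel_size, self.origin)


@dataclass
class SequenceTriplet:
    mrc: Volume
    ppi: Volume
    pei: Volume

    def __post_init__(self) -> None:
        self.mrc.require_same_grid(self.ppi, "MRC vs PPI")
        self.mrc.require_same_grid(self.pei, "MRC vs PEI")


def _spiral_points(c: CochleaSpec, t: np.ndarray) -> np.ndarray:
    """Centerline samples in mm, relative to the cochlea center, for the
    *right* ear.  Columns are (axis0, axis1, axis2)."""
    theta = 2.0 * np.pi * c.turns * t
    r = c.base_radius_mm * (1.0 - 0.75 * t)
    x0 = r * np.cos(theta)
    x2 = r * np.sin(theta)
    x1 = c.rise_mm * (t - 0.5)
    return np.column_stack([x0, x1, x2])


def _grid_axes(shape, voxel_size, origin):
    return [
        origin[a] + (np.arange(shape[a]) + 0.5) * voxel_size[a] for a in range(3)
    ]


def _check_fits(spec: PhantomSpec) -> None:
    ext = np.asarray(spec.extent_mm)
    reach = np.zeros(3)
    cv = np.abs(np.asarray(spec.vestibule.center_offset_mm)) + np.asarray(
        spec.vestibule.semi_axes_mm
    )
    spiral_reach = spec.cochlea.base_radius_mm + spec.cochlea.tube_radius_mm
    cc = np.abs(np.asarray(spec.cochlea.center_offset_mm)) + np.array(
        [spiral_reach, 0.5 * spec.cochlea.rise_mm + spec.cochlea.tube_radius_mm, spiral_reach]
    )
    reach = np.maximum(cv, cc)
    for side, center in spec.ear_centers_mm().items():
        lo = center - reach
        hi = center + reach
        for ax in range(3):
            if lo[ax] < 0 or hi[ax] > ext[ax]:
                raise ValueError(
                    f"labyrinth geometry ({side} ear) exceeds the grid along axis {ax}: "
                    f"needs [{lo[ax]:.1f}, {hi[ax]:.1f}] mm, grid extent {ext[ax]:.1f} mm"
                )


def _rank_quantile(depth: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean selector of the ``fraction`` smallest entries of ``depth``.

    Using a rank cut (rather than a value cut) recovers the requested volume
    fraction to within one voxel regardless of discretization.
    """
    n = depth.size
    k = int(round(fraction * n))
    if k <= 0:
        return np.zeros(n, dtype=bool)
    order = np.argsort(depth, kind="stable")
    sel = np.zeros(n, dtype=bool)
    sel[order[:k]] = True
    return sel


def _rasterize_vestibule(spec: PhantomSpec, center: np.ndarray, axes, frac: float):
    a0, a1, a2 = spec.vestibule.semi_axes_mm
    off = np.asarray(spec.vestibule.center_offset_mm)
    c = center + off
    d0 = (axes[0] - c[0]) / a0
    d1 = (axes[1] - c[1]) / a1
    d2 = (axes[2] - c[2]) / a2
    q = (
        d0[:, None, None] ** 2
        + d1[None, :, None] ** 2
        + d2[None, None, :] ** 2
    )
    inside = q <= 1.0
    # normalized in-slice (axes 0 and 2) radius relative to the slice boundary,
    # so every grading slice carries the same endolymph area fraction
    inplane = d0[:, None, None] ** 2 + np.zeros((1, len(axes[1]), 1)) + d2[None, None, :] ** 2
    height = 1.0 - (d1**2)[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(height > 0, inplane / np.maximum(height, 1e-12), np.inf)
    endo = np.zeros_like(inside)
    idx = np.nonzero(inside)
    if idx[0].size:
        sel = _rank_quantile(depth[idx], frac)
        endo[idx] = sel
    return inside, endo


def _rasterize_cochlea(spec: PhantomSpec, center: np.ndarray, axes, frac: float, mirror: bool):
    c = center + np.asarray(spec.cochlea.center_offset_mm)
    t = np.linspace(0.0, 1.0, 4000)
    pts = _spiral_points(spec.cochlea, t)
    if mirror:
        pts = pts * np.array([1.0, 1.0, -1.0])
    pts = pts + c
    rt = spec.cochlea.tube_radius_mm
    # candidate voxels: bounding box of the spiral plus tube radius
    lo = pts.min(axis=0) - rt
    hi = pts.max(axis=0) + rt
    sub = []
    for ax in range(3):
        sub.append(np.nonzero((axes[ax] >= lo[ax]) & (axes[ax] <= hi[ax]))[0])
    if any(s.size == 0 for s in sub):
        shape = tuple(len(a) for a in axes)
        return np.zeros(shape, bool), np.zeros(shape, bool)
    g0, g1, g2 = np.meshgrid(axes[0][sub[0]], axes[1][sub[1]], axes[2][sub[2]], indexing="ij")
    pts_vox = np.column_stack([g0.ravel(), g1.ravel(), g2.ravel()])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts_vox, k=1)
    inside_flat = dist <= rt
    shape = tuple(len(a) for a in axes)
    inside = np.zeros(shape, bool)
    endo = np.zeros(shape, bool)
    ii, jj, kk = np.meshgrid(sub[0], sub[1], sub[2], indexing="ij")
    flat_idx = (ii.ravel(), jj.ravel(), kk.ravel())
    inside[flat_idx] = inside_flat
    if inside_flat.any():
        # per-slice quantile along the grading axis: every axial slice of the
        # duct carries the requested endolymph area fraction, so the graded
        # area ratio matches the volume fraction
        depth = dist / rt
        slice_idx = jj.ravel()
        endo_flat = np.zeros_like(inside_flat)
        for j in np.unique(slice_idx[inside_flat]):
            sel_slice = inside_flat & (slice_idx == j)
            rows = np.nonzero(sel_slice)[0]
            keep = _rank_quantile(depth[rows], frac)
            endo_flat[rows[keep]] = True
        endo[flat_idx] = endo_flat
    return inside, endo


def build_labyrinth(spec: PhantomSpec, grid=None) -> LabyrinthMask:
    """Rasterize the two mirrored labyrinths.

    ``grid`` optionally overrides the target raster as a
    ``(shape, voxel_size, origin)`` triple in the same world frame as the
    spec grid (used to obtain ground truth on the cropped/rescaled analysis
    grid); geometry stays defined by the spec.
    """
    if grid is None:
        _check_fits(spec)
        shape = tuple(spec.grid_shape)
        voxel = (spec.voxel_size_mm,) * 3
        origin = (0.0, 0.0, 0.0)
    else:
        shape, voxel, origin = grid
        shape = tuple(int(s) for s in shape)
        voxel = tuple(float(v) for v in voxel)
        origin = tuple(float(o) for o in origin)
    axes = _grid_axes(shape, voxel, origin)
    label = np.zeros(shape, np.uint8)
    comp = np.zeros(shape, np.uint8)
    side_vol = np.zeros(shape, np.uint8)
    centers = spec.ear_centers_mm()
    mid2 = 0.5 * spec.extent_mm[2]  # mirror plane between the ears
    for side, side_code in (("left", SIDE_LEFT), ("right", SIDE_RIGHT)):
        i = 0 if side == "left" else 1
        center = centers[side]
        # exact mirror symmetry: evaluate the left ear in mirrored coordinates
        if side == "left":
            axes_side = [axes[0], axes[1], (2.0 * mid2 - axes[2])[::-1]]
        else:
            axes_side = axes
        center_side = center.copy()
        if side == "left":
            center_side[2] = 2.0 * mid2 - center[2]
        v_in, v_endo = _rasterize_vestibule(
            spec, center_side, axes_side, spec.vestibule.endolymph_fraction[i]
        )
        c_in, c_endo = _rasterize_cochlea(
            spec, center_side, axes_side, spec.cochlea.endolymph_fraction[i], mirror=False
        )
        if side == "left":  # un-mirror back to grid order
            v_in, v_endo = v_in[:, :, ::-1], v_endo[:, :, ::-1]
            c_in, c_endo = c_in[:, :, ::-1], c_endo[:, :, ::-1]
        c_in &= ~v_in  # vestibule wins any (unexpected) overlap
        c_endo &= c_in
        fluid = v_in | c_in
        endo = v_endo | c_endo
        label[fluid] = PERILYMPH
        label[endo] = ENDOLYMPH
        comp[c_in] = COMP_COCHLEA
        comp[v_in] = COMP_VESTIBULE
        side_vol[fluid] = side_code
    return LabyrinthMask(label, comp, side_vol, voxel, origin)


def simulate_sequences(mask: LabyrinthMask, spec: PhantomSpec) -> SequenceTriplet:
    """Piecewise-constant intensities per tissue class plus Gaussian noise.

    MRC is bright over all fluid; PPI bright over perilymph and dark over
    endolymph; PEI the reverse, so PPI - PEI carries the endolymph sign.
    """
    means = spec.intensity.means
    vols = {}
    for seq in SEQUENCES:
        img = np.full(mask.label.shape, means["background"][seq], dtype=np.float64)
        img[mask.label == PERILYMPH] = means["perilymph"][seq]
        img[mask.label == ENDOLYMPH] = means["endolymph"][seq]
        sd = float(spec.intensity.noise_sd.get(seq, 0.0))
        if sd > 0:
            rng = substream(spec.seed, "noise", seq)
            img = img + rng.normal(0.0, sd, size=img.shape)
        vols[seq] = Volume(img, mask.voxel_size, mask.origin)
    return SequenceTriplet(**vols)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

SIDES = ("left", "right")
GROUPS = ("VM", "MD", "VM-MD")


@dataclass
class NeurotologyRecord:
    """Scalar neurotologic measures per subject (already-extracted values)."""

    r30: float
    r44: float
    l30: float
    l44: float
    cvemp_p13_amp_r: float
    cvemp_p13_amp_l: float
    cvemp_n23_amp_r: float
    cvemp_n23_amp_l: float
    cvemp_p13_lat_r: float
    cvemp_p13_lat_l: float
    cvemp_n23_lat_r: float
    cvemp_n23_lat_l: float
    ovemp_n10_amp_r: float
    ovemp_n10_amp_l: float
    ovemp_p15_amp_r: float
    ovemp_p15_amp_l: float
    ovemp_n10_lat_r: float
    ovemp_n10_lat_l: float
    ovemp_p15_lat_r: float
    ovemp_p15_lat_l: float
    pta_r: float
    pta_l: float
    low_tone_r: bool
    low_tone_l: bool
    vhit_gain_r: float
    vhit_gain_l: float


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    leading_side: str
    spec: PhantomSpec
    neurotology: NeurotologyRecord

    def build_truth(self) -> LabyrinthMask:
        return build_labyrinth(self.spec)

    def build_triplet(self, mask: LabyrinthMask | None = None) -> SequenceTriplet:
        return simulate_sequences(mask or self.build_truth(), self.spec)

    @property
    def true_els_ratio_ipsi(self) -> float:
        return self.spec.true_els_ratio(self.leading_side)


def _frac_ranges() -> dict[str, dict[str, tuple[float, float]]]:
    # (low, high) uniform ranges for endolymph fractions per group;
    # 'ipsi' applies to the clinically leading side
    # healthy endolymph fractions sit near the imaging detection limit (the
    # normal scala media is a sub-voxel structure), hydropic ears well above
    return {
        "VM": {
            "vest_ipsi": (0.05, 0.18),
            "coch_ipsi": (0.02, 0.06),
            "vest_contra": (0.05, 0.18),
            "coch_contra": (0.02, 0.06),
        },
        "MD": {
            "vest_ipsi": (0.35, 0.65),
            "coch_ipsi": (0.25, 0.55),
            "vest_contra": (0.08, 0.18),
            "coch_contra": (0.02, 0.06),
        },
        "VM-MD": {
            "vest_ipsi": (0.08, 0.35),
            "coch_ipsi": (0.03, 0.20),
            "vest_contra": (0.08, 0.18),
            "coch_contra": (0.02, 0.06),
        },
    }


@dataclass
class EffectModel:
    """Monotone links from ground-truth endolymph ratio to neurotology.

    A single per-subject severity scalar drives both the endolymph fractions
    (within group-specific ranges) and, through it, PTA (up), caloric
    slow-phase velocity (down), VEMP amplitudes (down) and vHIT gain (down)
    on the leading side.  ``*_sd`` values are additive Gaussian measurement
    noise; with all noise at 0 the links are strictly monotone and rank
    correlations are exactly +/-1.
    """

    pta_base_db: float = 12.0
    pta_slope_db: float = 55.0  # dB per unit cochlear endolymph fraction
    caloric_base: float = 26.0  # deg/s, sum of both irrigations per ear
    caloric_slope: float = -28.0  # per unit vestibular endolymph fraction
    cvemp_amp_base: float = 18.0  # microvolt
    ovemp_amp_base: float = 10.0
    vemp_amp_slope: float = -0.9  # relative reduction per unit fraction
    vhit_base: float = 0.96
    vhit_slope: float = -0.12
    pta_sd: float = 3.0
    caloric_sd: float = 1.5
    vemp_sd: float = 1.5
    vhit_sd: float = 0.03
    frac_ranges: dict = field(default_factory=_frac_ranges)


def _subject_neurotology(
    em: EffectModel,
    fracs: dict[str, dict[str, float]],
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> NeurotologyRecord:
    vols = spec.compartment_volumes_mm3()
    vtot = vols["vestibule"] + vols["cochlea"]

    def ratio(side: str) -> float:
        return (
            fracs[side]["vest"] * vols["vestibule"] + fracs[side]["coch"] * vols["cochlea"]
        ) / vtot

    out: dict[str, float | bool] = {}
    for side, suffix in (("right", "r"), ("left", "l")):
        v = fracs[side]["vest"]
        c = fracs[side]["coch"]
        r = ratio(side)
        pta = em.pta_base_db + em.pta_slope_db * c + rng.normal(0, em.pta_sd)
        caloric = max(em.caloric_base + em.caloric_slope * v + rng.normal(0, em.caloric_sd), 1.0)
        cv_amp = max(em.cvemp_amp_base * (1 + em.vemp_amp_slope * v) + rng.normal(0, em.vemp_sd), 0.1)
        ov_amp = max(em.ovemp_amp_base * (1 + em.vemp_amp_slope * v) + rng.normal(0, em.vemp_sd), 0.1)
        gain = em.vhit_base + em.vhit_slope * v + rng.normal(0, em.vhit_sd)
        out[f"pta_{suffix}"] = max(pta, 0.0)
        out[f"low_tone_{suffix}"] = bool(c >= 0.30)
        out[f"vhit_gain_{suffix}"] = float(gain)
        out[f"cvemp_p13_amp_{suffix}"] = float(cv_amp)
        out[f"cvemp_n23_amp_{suffix}"] = float(0.8 * cv_amp + rng.normal(0, 0.5 * em.vemp_sd))
        out[f"ovemp_n10_amp_{suffix}"] = float(ov_amp)
        out[f"ovemp_p15_amp_{suffix}"] = float(0.7 * ov_amp + rng.normal(0, 0.5 * em.vemp_sd))
        # latencies do not depend on hydrops (no group effect reported)
        out[f"cvemp_p13_lat_{suffix}"] = float(rng.normal(13.8, 0.5))
        out[f"cvemp_n23_lat_{suffix}"] = float(rng.normal(21.0, 1.0))
        out[f"ovemp_n10_lat_{suffix}"] = float(rng.normal(10.5, 0.6))
        out[f"ovemp_p15_lat_{suffix}"] = float(rng.normal(15.0, 0.8))
        if side == "right":
            out["r30"] = float(0.48 * caloric)
            out["r44"] = float(0.52 * caloric)
        else:
            out["l30"] = float(0.48 * caloric)
            out["l44"] = float(0.52 * caloric)
    return NeurotologyRecord(**out)  # type: ignore[arg-type]


def generate_cohort(
    group_sizes: dict[str, int],
    effect_model: EffectModel | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[SyntheticSubject]:
    """Generate a synthetic cohort with known ground truth.

    ``group_sizes`` maps group names ("VM", "MD", "VM-MD") to counts.  Every
    subject carries a :class:`PhantomSpec` (imaging ground truth) and a
    :class:`NeurotologyRecord` linked to it by the effect model.
    """
    em = effect_model or EffectModel()
    base = base_spec or PhantomSpec()
    subjects: list[SyntheticSubject] = []
    for group, n in group_sizes.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        if n < 0:
            raise ValueError(f"negative group size for {group}: {n}")
    idx = 0
    for group in GROUPS:
        n = int(group_sizes.get(group, 0))
        rng_group = substream(seed, "cohort", group)
        for j in range(n):
            sid = f"{group}-{j + 1:03d}"
            rng = substream(seed, "subject", sid)
            # leading side: random coin, as for clinically symmetric subjects
            leading = "left" if int(rng.integers(1, 10)) % 2 == 0 else "right"
            severity = float(rng.uniform())
            ranges = em.frac_ranges[group]

            def _lin(lo_hi: tuple[float, float]) -> float:
                lo, hi = lo_hi
                return lo + severity * (hi - lo)

            contra = "right" if leading == "left" else "left"
            fracs = {
                leading: {"vest": _lin(ranges["vest_ipsi"]), "coch": _lin(ranges["coch_ipsi"])},
                contra: {"vest": _lin(ranges["vest_contra"]), "coch": _lin(ranges["coch_contra"])},
            }
            spec = PhantomSpec(
                grid_shape=base.grid_shape,
                voxel_size_mm=base.voxel_size_mm,
                ear_separation_mm=base.ear_separation_mm,
                cochlea=CochleaSpec(
                    **{
                        **asdict(base.cochlea),
                        "endolymph_fraction": (fracs["left"]["coch"], fracs["right"]["coch"]),
                    }
                ),
                vestibule=VestibuleSpec(
                    **{
                        **asdict(base.vestibule),
                        "endolymph_fraction": (fracs["left"]["vest"], fracs["right"]["vest"]),
                    }
                ),
                intensity=base.intensity,
                seed=int(rng_group.integers(0, 2**31 - 1)),
            )
            neuro = _subject_neurotology(em, fracs, spec, substream(seed, "neuro", sid))
            subjects.append(SyntheticSubject(sid, group, leading, spec, neuro))
            idx += 1
    return subjects


def cohort_to_dataframe(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "leading_side": s.leading_side,
            "coch_frac_left": s.spec.cochlea.endolymph_fraction[0],
            "coch_frac_right": s.spec.cochlea.endolymph_fraction[1],
            "vest_frac_left": s.spec.vestibule.endolymph_fraction[0],
            "vest_frac_right": s.spec.vestibule.endolymph_fraction[1],
            "true_els_ratio_left": s.spec.true_els_ratio("left"),
            "true_els_ratio_right": s.spec.true_els_ratio("right"),
        }
        row.update(asdict(s.neurotology))
        rows.append(row)
    return pd.DataFrame(rows)
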