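"""ELS-derived parameters and semi-quantitative hydrops grading.

Volumetric parameters per side (ipsilateral / contralateral) and scope
(inner ear, cochlea, vestibule): ELS volume in mm^3, ELS/TFS ratio in %,
the between-side difference Diff = |ipsi - contra|, Diff/TFS ratio, and a
signed asymmetry index AI = 100 * (R - L) / (R + L).

Grading follows the two-threshold area-ratio scheme on single slices:
vestibular grade 0 when the ELS/TFS area ratio at the reference slice is
below 1/3, grade 1 up to 50%, grade 2 above; cochlear grades compare the
endolymph-classified (cochlear-duct) area against the remaining perilymph
(scala-vestibuli) area at the mid-modiolar slice.  Reference slices are
picked deterministically: the cochlear slice maximizes the cochlear fluid
cross-section; the vestibular slice is the lowest slice whose vestibular
fluid cross-section still exceeds half its maximum (a canal-free surrogate
for "lowest slice where the lateral semicircular canal is just visible",
since phantoms omit the canals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import BinaryHull
from .volt import ElsMask
from .volume import Volume

__all__ = [
    "ElsMeasures",
    "GradeResult",
    "els_volume",
    "asymmetry_index",
    "diff_and_ratio",
    "grade_vestibule",
    "grade_cochlea",
    "select_grading_slices",
    "compute_els_measures",
    "grade_side",
]

SCOPES = ("inner_ear", "cochlea", "vestibule")
VESTIBULAR_MILD_THRESHOLD = 1.0 / 3.0
VESTIBULAR_SEVERE_THRESHOLD = 0.5
COCHLEAR_DETECTION_FLOOR = 0.05  # fraction of the slice fluid area


def els_volume(mask, voxel_size=None) -> float:
    """Volume of a binary mask in mm^3 (voxel count x voxel volume)."""
    if isinstance(mask, Volume):
        return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3
    return float(np.count_nonzero(mask)) * float(np.prod(voxel_size))


def asymmetry_index(els_r: float, els_l: float) -> float:
    """Signed asymmetry index 100 * (R - L) / (R + L), in %; 0 when both 0."""
    if els_r < 0 or els_l < 0:
        raise ValueError("volumes must be non-negative")
    total = els_r + els_l
    if total == 0:
        return 0.0
    return 100.0 * (els_r - els_l) / total


def diff_and_ratio(els_i: float, els_c: float, tfs_mean: float) -> tuple[float, float]:
    """Absolute between-side difference and its ratio to the mean TFS, in %."""
    if tfs_mean <= 0:
        raise ValueError("mean TFS must be positive")
    diff = abs(els_i - els_c)
    return diff, 100.0 * diff / tfs_mean


def grade_vestibule(area_ratio: float) -> int:
    """Vestibular grade from the ELS/TFS area ratio at the reference slice.

    Below 1/3 -> 0 (none); up to and including 50% -> 1 (mild);
    above 50% -> 2 (severe).  The 50% boundary is mild ("exceeds 50%" is
    read strictly).
    """
    if not 0.0 <= area_ratio <= 1.0:
        raise ValueError(f"area ratio {area_ratio} outside [0, 1]")
    if area_ratio < VESTIBULAR_MILD_THRESHOLD:
        return 0
    if area_ratio <= VESTIBULAR_SEVERE_THRESHOLD:
        return 1
    return 2


def grade_cochlea(duct_area: float, scala_vestibuli_area: float, detection_floor: float = 0.0) -> int:
    """Cochlear grade: duct (endolymph) area vs scala-vestibuli area.

    Below the detection floor -> 0; as large as the scala vestibuli
    (duct <= SV) -> 1; larger -> 2.
    """
    if duct_area < 0 or scala_vestibuli_area < 0:
        raise ValueError("areas must be non-negative")
    if duct_area < detection_floor or duct_area == 0:
        return 0
    if duct_area <= scala_vestibuli_area:
        return 1
    return 2


def _slice_areas(mask: np.ndarray, axis: int) -> np.ndarray:
    other = tuple(a for a in range(3) if a != axis)
    return np.count_nonzero(mask, axis=other) if mask.ndim == 3 else np.asarray([])


def select_grading_slices(
    tfs_cochlea: np.ndarray, tfs_vestibule: np.ndarray, axis: int = 1
) -> tuple[int, int]:
    """Deterministic reference slices for grading (one side at a time).

    Cochlear: the slice with the largest cochlear fluid cross-section
    (mid-modiolar surrogate).  Vestibular: the lowest slice whose
    vestibular fluid cross-section exceeds half its maximum.  Ties break
    toward the lower index.
    """
    areas_c = _slice_areas(np.asarray(tfs_cochlea, dtype=bool), axis)
    areas_v = _slice_areas(np.asarray(tfs_vestibule, dtype=bool), axis)
    if areas_c.sum() == 0:
        raise ValueError("empty cochlear compartment")
    if areas_v.sum() == 0:
        raise ValueError("empty vestibular compartment")
    cochlear_slice = int(np.argmax(areas_c))  # argmax takes the first maximum
    half_max = 0.5 * areas_v.max()
    vestibular_slice = int(np.nonzero(areas_v > half_max)[0][0])
    return cochlear_slice, vestibular_slice


@dataclass
class GradeResult:
    cochlear_grade: int
    vestibular_grade: int
    cochlear_slice: int
    vestibular_slice: int
    cochlear_duct_area_vox: float
    scala_vestibuli_area_vox: float
    vestibular_area_ratio: float

    @property
    def max_grade(self) -> int:
        return max(self.cochlear_grade, self.vestibular_grade)


def _take(mask: np.ndarray, axis: int, index: int) -> np.ndarray:
    return np.take(mask, index, axis=axis)


def grade_side(
    els_cochlea: np.ndarray,
    els_vestibule: np.ndarray,
    tfs_cochlea: np.ndarray,
    tfs_vestibule: np.ndarray,
    axis: int = 1,
    detection_floor_fraction: float = COCHLEAR_DETECTION_FLOOR,
) -> GradeResult:
    """Grade one ear from its compartment ELS and TFS masks."""
    c_idx, v_idx = select_grading_slices(tfs_cochlea, tfs_vestibule, axis)
    coch_fluid = np.count_nonzero(_take(np.asarray(tfs_cochlea, bool), axis, c_idx))
    duct = np.count_nonzero(
        _take(np.asarray(els_cochlea, bool) & np.asarray(tfs_cochlea, bool), axis, c_idx)
    )
    sv = coch_fluid - duct  # remaining (perilymph) area at the slice
    floor = detection_floor_fraction * coch_fluid
    vest_fluid = np.count_nonzero(_take(np.asarray(tfs_vestibule, bool), axis, v_idx))
    vest_els = np.count_nonzero(
        _take(np.asarray(els_vestibule, bool) & np.asarray(tfs_vestibule, bool), axis, v_idx)
    )
    ratio = vest_els / vest_fluid if vest_fluid else 0.0
    return GradeResult(
        cochlear_grade=grade_cochlea(duct, sv, floor),
        vestibular_grade=grade_vestibule(min(ratio, 1.0)),
        cochlear_slice=c_idx,
        vestibular_slice=v_idx,
        cochlear_duct_area_vox=float(duct),
        scala_vestibuli_area_vox=float(sv),
        vestibular_area_ratio=float(ratio),
    )


@dataclass
class ElsMeasures:
    """Per-side, per-scope ELS/TFS volumes and the derived side-relation
    parameters.  Sides are keyed "left"/"right"; ``leading_side`` maps them
    to ipsilateral/contralateral."""

    els_mm3: dict = field(default_factory=dict)  # (side, scope) -> mm3
    tfs_mm3: dict = field(default_factory=dict)
    els_tfs_ratio_pct: dict = field(default_factory=dict)
    diff_mm3: dict = field(default_factory=dict)  # scope -> mm3
    diff_tfs_ratio_pct: dict = field(default_factory=dict)
    asymmetry_index_pct: dict = field(default_factory=dict)  # signed R - L
    grades: dict = field(default_factory=dict)  # side -> GradeResult
    leading_side: str = "right"

    def side_for(self, role: str) -> str:
        if role == "ipsilateral":
            return self.leading_side
        return "left" if self.leading_side == "right" else "right"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (side, scope), els in sorted(self.els_mm3.items()):
            rows.append(
                {
                    "side": side,
                    "scope": scope,
                    "els_mm3": els,
                    "tfs_mm3": self.tfs_mm3[(side, scope)],
                    "els_tfs_ratio_pct": self.els_tfs_ratio_pct[(side, scope)],
                    "diff_mm3": self.diff_mm3[scope],
                    "diff_tfs_ratio_pct": self.diff_tfs_ratio_pct[scope],
                    "asymmetry_index_pct": self.asymmetry_index_pct[scope],
                }
            )
        return pd.DataFrame(rows)


def compute_els_measures(
    els: ElsMask,
    hull: BinaryHull,
    compartments: Volume,
    leading_side: str = "right",
    grading_axis: int = 1,
) -> ElsMeasures:
    """All volumetric parameters plus grades for one subject.

    ``hull.side`` supplies the left/right split of the TFS;
    ``compartments`` (1 = cochlea, 2 = vestibule) supplies the compartment
    split of both the TFS and the ELS classification.
    """
    if hull.side is None:
        raise ValueError("hull must carry a side labeling")
    vox = els.mask.voxel_volume_mm3
    side_arr = np.asarray(hull.side.data)
    hull_arr = np.asarray(hull.mask.data, dtype=bool)
    comp = np.asarray(compartments.data)
    els_arr = np.asarray(els.mask.data, dtype=bool) & hull_arr
    out = ElsMeasures(leading_side=leading_side)
    scope_sel = {
        "inner_ear": np.ones_like(hull_arr),
        "cochlea": comp == 1,
        "vestibule": comp == 2,
    }
    for side_name, code in (("left", 1), ("right", 2)):
        s = side_arr == code
        for scope, sel in scope_sel.items():
            tfs = np.count_nonzero(hull_arr & s & sel) * vox
            ev = np.count_nonzero(els_arr & s & sel) * vox
            out.els_mm3[(side_name, scope)] = ev
            out.tfs_mm3[(side_name, scope)] = tfs
            out.els_tfs_ratio_pct[(side_name, scope)] = 100.0 * ev / tfs if tfs else 0.0
        out.grades[side_name] = grade_side(
            els_arr & s & (comp == 1),
            els_arr & s & (comp == 2),
            hull_arr & s & (comp == 1),
            hull_arr & s & (comp == 2),
            axis=grading_axis,
        )
    ipsi = leading_side
    contra = "left" if ipsi == "right" else "right"
    for scope in SCOPES:
        tfs_mean = 0.5 * (out.tfs_mm3[("left", scope)] + out.tfs_mm3[("right", scope)])
        diff, ratio = diff_and_ratio(
            out.els_mm3[(ipsi, scope)], out.els_mm3[(contra, scope)], tfs_mean
        )
        out.diff_mm3[scope] = diff
        out.diff_tfs_ratio_pct[scope] = ratio
        out.asymmetry_index_pct[scope] = asymmetry_index(
            out.els_mm3[("right", scope)], out.els_mm3[("left", scope)]
        )
    return out
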