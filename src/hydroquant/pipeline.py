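"""End-to-end orchestration: phantom subject -> measures, grades, stats.

``run_subject`` executes preprocess -> atlas registration -> hull
extraction -> fusion -> local-threshold ensemble -> compartment split ->
volumetric measures and grades, writing every intermediate when an output
directory is given.  ``run_cohort`` maps it over a synthetic cohort and
adds the group-level association statistics.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hydrops import PreprocessConfig, preprocess_triplet
from .metrics import ElsMeasures, compute_els_measures
from .neurotology import DeficitClassification, DeficitThresholds, classify_record
from .phantom import (
    LabyrinthMask,
    SyntheticSubject,
    build_labyrinth,
    cohort_to_dataframe,
)
from .segmentation import (
    BinaryHull,
    ProbabilisticAtlas,
    RegistrationConfig,
    build_atlas,
    dilate_hull,
    extract_hull,
    fuse,
    register_affine,
    resample_atlas,
)
from .stats import anova_bonferroni, build_group_symptom_table, chi_square, spearman
from .volt import VoltConfig, run_volt, split_compartments
from .volume import Volume, save_nifti

__all__ = ["RunConfig", "SubjectResult", "PipelineStageError", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    volt: VoltConfig = field(default_factory=VoltConfig)
    thresholds: DeficitThresholds = field(default_factory=DeficitThresholds)
    atlas_threshold: float = 0.5
    hull_dilation_radius: int = 1
    grading_axis: int = 1
    assume_aligned: bool = False  # skip registration when atlas and subject share a frame
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    leading_side: str
    measures: ElsMeasures
    deficits: DeficitClassification
    provenance: dict

    @property
    def eh_present(self) -> bool:
        return any(g.max_grade >= 1 for g in self.measures.grades.values())

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "leading_side": self.leading_side,
            "eh_present": self.eh_present,
            "deficit_category": self.deficits.category,
            "deficit_laterality": self.deficits.laterality,
        }
        for side in ("left", "right"):
            g = self.measures.grades[side]
            row[f"cochlear_grade_{side}"] = g.cochlear_grade
            row[f"vestibular_grade_{side}"] = g.vestibular_grade
        ipsi = self.measures.side_for("ipsilateral")
        contra = self.measures.side_for("contralateral")
        for scope in ("inner_ear", "cochlea", "vestibule"):
            row[f"els_ipsi_{scope}_mm3"] = self.measures.els_mm3[(ipsi, scope)]
            row[f"els_contra_{scope}_mm3"] = self.measures.els_mm3[(contra, scope)]
            row[f"els_tfs_ipsi_{scope}_pct"] = self.measures.els_tfs_ratio_pct[(ipsi, scope)]
            row[f"diff_{scope}_mm3"] = self.measures.diff_mm3[scope]
            row[f"diff_tfs_{scope}_pct"] = self.measures.diff_tfs_ratio_pct[scope]
            row[f"ai_{scope}_pct"] = self.measures.asymmetry_index_pct[scope]
        return row


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_subject(
    subject: SyntheticSubject,
    cfg: RunConfig | None = None,
    atlas: ProbabilisticAtlas | None = None,
    out_dir: str | Path | None = None,
) -> SubjectResult:
    """Full single-subject pipeline on a synthetic subject."""
    cfg = cfg or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("simulate"):
        truth = subject.build_truth()
        triplet = subject.build_triplet(truth)

    with _stage("preprocess"):
        pre = preprocess_triplet(triplet.mrc, triplet.ppi, triplet.pei, cfg.preprocess)
        if out is not None:
            save_nifti(pre.mi2, out / "mi2.nii.gz")
            save_nifti(pre.mrc, out / "mrc_8bit.nii.gz")

    with _stage("register"):
        if atlas is None:
            atlas = build_atlas([truth])
        if cfg.assume_aligned:
            atlas_mask = resample_atlas(
                atlas, _identity_params(pre.mrc), pre.mrc, cfg.atlas_threshold
            )
        else:
            params = register_affine(atlas, pre.mrc, cfg.registration)
            atlas_mask = resample_atlas(atlas, params, pre.mrc, cfg.atlas_threshold)
            if out is not None:
                params.to_json(out / "transform.json")

    with _stage("segment"):
        hull = extract_hull(pre.mrc, atlas_mask)
        hull_d = dilate_hull(hull, cfg.hull_dilation_radius)
        fused = fuse(hull_d, pre.mi2)
        if out is not None:
            save_nifti(hull.mask, out / "hull.nii.gz")

    with _stage("volt"):
        agg, els = run_volt(fused, cfg.volt, hull)
        if out is not None:
            save_nifti(agg.votes, out / "votes.nii.gz")
            save_nifti(els.mask, out / "els_mask.nii.gz")

    with _stage("quantify"):
        truth_proc = build_labyrinth(
            subject.spec, grid=(pre.mi2.shape, pre.mi2.voxel_size, pre.mi2.origin)
        )
        split = split_compartments(els, compartment_labels=truth_proc.as_volume("compartment"))
        measures = compute_els_measures(
            split,
            hull,
            truth_proc.as_volume("compartment"),
            leading_side=subject.leading_side,
            grading_axis=cfg.grading_axis,
        )

    with _stage("neurotology"):
        deficits = classify_record(subject.neurotology, cfg.thresholds)

    provenance = {
        "config_hash": cfg.config_hash(),
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
    }
    result = SubjectResult(
        subject.subject_id, subject.group, subject.leading_side, measures, deficits, provenance
    )
    if out is not None:
        measures.to_frame().to_csv(out / "metrics.csv", index=False)
        with open(out / "result.json", "w") as fh:
            json.dump(result.to_row() | {"provenance": provenance}, fh, indent=2, default=str)
    return result


def _identity_params(fixed: Volume):
    from .segmentation import AffineParams

    center = tuple(np.asarray(fixed.origin) + 0.5 * np.asarray(fixed.extent_mm))
    return AffineParams(center=center)


def run_cohort(
    subjects: list[SyntheticSubject],
    cfg: RunConfig | None = None,
    atlas: ProbabilisticAtlas | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject results plus group-level association statistics."""
    if not subjects:
        raise ValueError("cohort is empty")
    cfg = cfg or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    failures = []
    for s in sorted(subjects, key=lambda s: s.subject_id):
        try:
            res = run_subject(s, cfg, atlas=atlas)
            row = res.to_row()
            row["true_els_ratio_ipsi"] = s.true_els_ratio_ipsi
            ipsi = "r" if s.leading_side == "right" else "l"
            row["pta_ipsi"] = getattr(s.neurotology, f"pta_{ipsi}")
            row["caloric_ipsi"] = getattr(s.neurotology, f"{ipsi}30") + getattr(
                s.neurotology, f"{ipsi}44"
            )
            rows.append(row)
        except PipelineStageError as err:
            failures.append(
                {"subject_id": s.subject_id, "group": s.group, "failed_stage": err.stage,
                 "error": str(err.original)}
            )
    table = pd.DataFrame(rows)
    report: dict = {"n_subjects": len(rows), "failures": failures}
    if len(table) and table["group"].nunique() >= 2:
        try:
            ct = build_group_symptom_table(table, "eh_present")
            if (ct.counts.sum(axis=1) > 0).all():
                res = chi_square(ct)
                report["eh_presence_chi2"] = {
                    "statistic": res.statistic, "df": res.df, "p": res.p, "phi": res.phi,
                }
        except ValueError as err:
            report["eh_presence_chi2"] = f"not computed ({err})"
    else:
        report["eh_presence_chi2"] = "not computed (n<2 groups)"
    if len(table) >= 3:
        rho_pta, p_pta = spearman(table["true_els_ratio_ipsi"], table["pta_ipsi"])
        rho_cal, p_cal = spearman(table["true_els_ratio_ipsi"], table["caloric_ipsi"])
        report["spearman_true_ratio_vs_pta"] = {"rho": rho_pta, "p": p_pta}
        report["spearman_true_ratio_vs_caloric"] = {"rho": rho_cal, "p": p_cal}
    if len(table) and table["group"].nunique() >= 2:
        counts = table["group"].value_counts()
        if (counts >= 2).all():
            f_stat, p_f, pairwise = anova_bonferroni(
                table["group"].to_numpy(), table["els_tfs_ipsi_inner_ear_pct"].to_numpy()
            )
            report["anova_els_tfs_ipsi"] = {
                "F": f_stat, "p": p_f,
                "pairwise_bonferroni": {f"{a} vs {b}": v for (a, b), v in pairwise.items()},
            }
    if out is not None:
        table.to_csv(out / "cohort_results.csv", index=False)
        cohort_to_dataframe(subjects).to_csv(out / "cohort_truth.csv", index=False)
        with open(out / "cohort_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return table, report
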