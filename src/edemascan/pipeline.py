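"""End-to-end orchestration: DICOM → skull strip → cranial perimeter →
propagation → CSF segmentation → volumetrics → longitudinal model.

The pipeline walks a cohort directory of per-subject DICOM sessions,
joins manual clinical readings (scan times, age, midline shift, CED
grade) from a CSV, and emits a scan-level cohort table, per-scan QC
overlays, an exclusion log (no silent drops: every excluded scan or
subject appears with a reason) and a machine-readable run report.
Re-running with identical inputs and config reproduces identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, brainx, csfseg, ingest, register, stats, volumetry
from .core import CTVolume, EdemascanError, MaskVolume, RegistrationFailure, load_ct_nifti, load_mask_nifti, write_json

__all__ = ["PipelineConfig", "run_pipeline", "load_atlas_dir"]

log = logging.getLogger("edemascan.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    """Paths, stage toggles, seeds and thresholds for one cohort run."""

    dicom_root: str
    clinical_csv: str
    out_dir: str
    atlas_dir: str | None = None
    model_bundle: str | None = None
    infarct_dir: str | None = None
    seed: int = 17
    qc_ratio: float = register.QC_RATIO_TOLERANCE
    probability_threshold: float = 0.5
    hu_window: tuple[float, float] = (0.0, 15.0)
    refine_iterations: int = 0
    write_overlays: bool = True
    run_gee: bool = True
    time_unit: str = "hours"

    def validate(self) -> None:
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise ValueError("probability_threshold must lie in [0, 1]")
        if self.qc_ratio < 0:
            raise ValueError("qc_ratio must be non-negative")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy lo < hi")
        if self.refine_iterations < 0:
            raise ValueError("refine_iterations must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_atlas_dir(atlas_dir: str | Path) -> register.AtlasSet:
    """Load paired ``template_XX_ct.nii.gz`` / ``template_XX_mask.nii.gz``."""
    atlas_dir = Path(atlas_dir)
    templates = []
    for ct_path in sorted(atlas_dir.glob("template_*_ct.nii.gz")):
        mask_path = Path(str(ct_path).replace("_ct.nii.gz", "_mask.nii.gz"))
        if not mask_path.exists():
            raise EdemascanError(f"atlas mask missing for {ct_path.name}")
        templates.append((load_ct_nifti(ct_path), load_mask_nifti(mask_path)))
    return register.AtlasSet(templates)


def _segment_scan(
    vol: CTVolume,
    cranial: MaskVolume,
    clf,
    config: PipelineConfig,
    infarct: MaskVolume | None,
) -> MaskVolume:
    if clf is not None:
        csf, _ = csfseg.predict_csf(vol, cranial, clf, threshold=config.probability_threshold)
    else:
        csf = csfseg.threshold_baseline_segment(vol, cranial, config.hu_window)
    if config.refine_iterations > 0:
        csf = csfseg.refine_active_contour(vol, csf, cranial=cranial, iterations=config.refine_iterations)
    if infarct is not None:
        csf = csfseg.clean_with_infarct_mask(csf, infarct)
    return csf


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage over the cohort; returns the run report dict.

    Stage failures are contained per scan/subject: the failing unit is
    excluded with a reason and the run continues.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = pd.read_csv(config.clinical_csv, dtype={"subject_id": str})
    atlas = load_atlas_dir(config.atlas_dir) if config.atlas_dir else None
    clf = csfseg.load_classifier(config.model_bundle) if config.model_bundle else None

    records: list[volumetry.ScanRecord] = []
    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "subjects": {},
        "stage_counts": {"subjects": 0, "scans_ingested": 0, "scans_segmented": 0, "scans_excluded": 0},
    }

    subject_dirs = sorted(p for p in Path(config.dicom_root).iterdir() if p.is_dir())
    for subj_dir in subject_dirs:
        sid = subj_dir.name.replace("sub-", "")
        report["stage_counts"]["subjects"] += 1
        subj_clin = clinical[clinical["subject_id"].astype(str) == sid].sort_values("scan_time_h")
        subj_report: dict = {"scans": [], "errors": []}
        report["subjects"][sid] = subj_report
        try:
            scans = _ingest_subject(subj_dir, subj_clin, report)
        except EdemascanError as exc:
            subj_report["errors"].append(f"ingest: {exc}")
            continue
        if not scans:
            subj_report["errors"].append("no analyzable scans")
            continue

        baseline_vol, baseline_row = scans[0]
        try:
            intracranial, _ = brainx.skull_strip(baseline_vol, seed=config.seed)
            if atlas is not None:
                cranial0 = register.multi_atlas_cranial_mask(
                    baseline_vol, atlas, seed=config.seed, intracranial=intracranial
                )
            else:
                cranial0 = intracranial
        except (EdemascanError, RegistrationFailure) as exc:
            subj_report["errors"].append(f"brain extraction: {exc}")
            continue

        base_cranial_ml = cranial0.volume_ml()
        for k, (vol, row) in enumerate(scans):
            flags = ""
            if k == 0:
                cranial = cranial0
            else:
                try:
                    cranial = register.propagate_mask_to_followup(
                        baseline_vol, cranial0, vol, seed=config.seed + k
                    )
                    if abs(cranial.volume_ml() / base_cranial_ml - 1.0) > config.qc_ratio:
                        flags = "registration failed: cranial volume ratio out of tolerance"
                except RegistrationFailure as exc:
                    flags = f"registration failed: {exc}"
            infarct = _load_infarct(config, sid, k, vol)
            csf_ml = cranial_ml = 0.0
            if not flags:
                csf_mask = _segment_scan(vol, cranial, clf, config, infarct)
                report["stage_counts"]["scans_segmented"] += 1
                csf_ml = csf_mask.volume_ml()
                cranial_ml = cranial.volume_ml()
                if config.write_overlays:
                    volumetry.render_overlay(
                        vol, csf_mask, out_dir / "overlays" / f"sub-{sid}_scan-{k}.png"
                    )
            else:
                report["stage_counts"]["scans_excluded"] += 1
            records.append(
                volumetry.ScanRecord(
                    subject_id=sid,
                    time_from_onset_h=float(row["scan_time_h"]),
                    cranial_ml=cranial_ml if not flags else 1.0,
                    csf_ml=csf_ml,
                    infarct_ml=infarct.volume_ml() if infarct is not None else None,
                    mls_mm=float(row["mls_mm"]) if "mls_mm" in row and pd.notna(row["mls_mm"]) else None,
                    ced_grade=int(row["ced_grade"]) if "ced_grade" in row and pd.notna(row["ced_grade"]) else None,
                    qc_flags=flags,
                )
            )
            subj_report["scans"].append({"index": k, "time_h": float(row["scan_time_h"]), "qc": flags or "pass"})

    table = volumetry.compile_cohort(records)
    cohort_csv = volumetry.export_cohort_csv(table, out_dir / "cohort.csv")
    table.subjects.to_csv(out_dir / "subjects.csv", index=False, float_format="%.6g")
    table.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    report["outputs"] = {
        "cohort_csv": str(cohort_csv),
        "subjects_csv": str(out_dir / "subjects.csv"),
        "exclusions_csv": str(out_dir / "exclusions.csv"),
    }
    report["stage_counts"]["scans_in_cohort"] = int(len(table.scans))
    report["stage_counts"]["subjects_in_cohort"] = int(len(table.subjects))
    report["stage_counts"]["exclusions"] = int(len(table.exclusions))

    if config.run_gee:
        merged = table.scans.merge(
            clinical[["subject_id", "scan_time_h", "age_years"]].assign(
                subject_id=lambda d: d["subject_id"].astype(str)
            ),
            on=["subject_id", "scan_time_h"],
            how="left",
        )
        enough = (
            len(table.subjects) >= 2
            and (table.scans.groupby("subject_id").size() >= 2).sum() >= 2
            and len(merged) > 6
        )
        if enough:
            try:
                design = stats.GeeDesign.from_frame(
                    merged.rename(columns={"scan_time_h": "time_days"}).assign(
                        time_days=lambda d: d["time_days"] / 24.0
                    ),
                    time_col="time_days",
                )
                fit = stats.fit_gee_markov(design)
                fit.summary_frame().to_csv(out_dir / "gee_coefficients.csv", index=False, float_format="%.8g")
                write_json(
                    {
                        "a": fit.a,
                        "sigma2": fit.sigma2,
                        "iterations": fit.iterations,
                        "converged": fit.converged,
                        "n_subjects": fit.n_subjects,
                        "n_obs": fit.n_obs,
                        "coefficients": dict(zip(fit.coef_names, fit.b.tolist())),
                    },
                    out_dir / "gee_report.json",
                )
                report["outputs"]["gee_report"] = str(out_dir / "gee_report.json")
            except EdemascanError as exc:
                report["gee_error"] = str(exc)
        else:
            report["gee_error"] = "insufficient data for the longitudinal model"

    write_json(report, out_dir / "run_report.json")
    return report


def _ingest_subject(subj_dir: Path, subj_clin: pd.DataFrame, report: dict):
    """Ingest each session directory; rows of the clinical table are matched
    to sessions in time order."""
    sessions = sorted(p for p in subj_dir.iterdir() if p.is_dir())
    scans = []
    for k, ses_dir in enumerate(sessions):
        series_list = ingest.load_dicom_dir(ses_dir)
        series = ingest.select_axial_brain_series(series_list)
        vol = ingest.ingest_series(series)
        if k >= len(subj_clin):
            raise EdemascanError(f"clinical table has no row for session {ses_dir.name}")
        scans.append((vol, subj_clin.iloc[k]))
        report["stage_counts"]["scans_ingested"] += 1
    scans.sort(key=lambda sv: float(sv[1]["scan_time_h"]))
    return scans


def _load_infarct(config: PipelineConfig, sid: str, scan_index: int, like: CTVolume) -> MaskVolume | None:
    if not config.infarct_dir:
        return None
    path = Path(config.infarct_dir) / f"sub-{sid}_scan-{scan_index}_infarct.nii.gz"
    if not path.exists():
        return None
    mask = load_mask_nifti(path)
    if mask.shape != like.shape:
        raise EdemascanError(f"infarct mask grid mismatch for {path.name}")
    return MaskVolume(mask.data, like.spacing, like.origin)
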