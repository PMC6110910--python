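"""Mask-to-volume conversion, per-subject edema metrics, QC overlays and
cohort-table export.

Volumes are voxel counts times the physical voxel volume from the image
header.  The headline edema metric is the maximal CSF reduction: the
lowest measured CSF volume as a percentage of the baseline (first-scan)
volume.  Midline shift and cerebral-edema (CED) grade are manual
radiologist readings and enter only as input columns.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CTVolume, EdemascanError, MaskVolume, require_same_grid

__all__ = [
    "ScanRecord",
    "CohortTable",
    "mask_volume_ml",
    "max_csf_reduction",
    "compile_cohort",
    "render_overlay",
    "export_cohort_csv",
    "load_cohort_csv",
    "COHORT_COLUMNS",
]

log = logging.getLogger("edemascan.volumetry")

FOLLOWUP_LATE_LIMIT_H = 168.0  # one week

COHORT_COLUMNS = [
    "subject_id",
    "scan_time_h",
    "cranial_ml",
    "csf_ml",
    "csf_pct",
    "infarct_ml",
    "mls_mm",
    "ced_grade",
    "qc_flags",
]


@dataclasses.dataclass
class ScanRecord:
    """One scan's volumetric and clinical row."""

    subject_id: str
    time_from_onset_h: float
    cranial_ml: float
    csf_ml: float
    infarct_ml: float | None = None
    mls_mm: float | None = None
    ced_grade: int | None = None
    qc_flags: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.csf_ml <= self.cranial_ml):
            raise ValueError(
                f"csf_ml must lie in [0, cranial_ml]: {self.csf_ml} vs {self.cranial_ml}"
            )
        if self.ced_grade is not None and self.ced_grade not in (0, 1, 2, 3):
            raise ValueError(f"CED grade must be 0..3, got {self.ced_grade}")
        if (
            self.ced_grade == 3
            and self.mls_mm is not None
            and self.mls_mm <= 0
        ):
            raise ValueError("CED grade 3 means swelling with midline shift; mls_mm must be > 0")

    @property
    def csf_pct(self) -> float:
        return 100.0 * self.csf_ml / self.cranial_ml


@dataclasses.dataclass
class CohortTable:
    """Scan-level table plus per-subject derived fields and exclusions."""

    scans: pd.DataFrame
    subjects: pd.DataFrame
    exclusions: pd.DataFrame


def mask_volume_ml(mask: MaskVolume | np.ndarray, spacing: Sequence[float] | None = None) -> float:
    """Voxel count × voxel volume, in ml."""
    if isinstance(mask, MaskVolume):
        return mask.volume_ml()
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    return float(np.asarray(mask, dtype=bool).sum() * np.prod(spacing) / 1000.0)


def max_csf_reduction(volumes_ml: Sequence[float]) -> tuple[float, float]:
    """(lowest volume as % of baseline, reduction %) for a time-ordered series.

    Baseline is the first scan.  When CSF never falls below baseline the
    reduction is floored at 0 (and logged), keeping the downstream
    quadratic shift model on a sane domain.
    """
    vols = [float(v) for v in volumes_ml]
    if len(vols) < 2:
        raise ValueError("need at least two volumes (baseline + follow-up)")
    if vols[0] <= 0:
        raise ValueError("baseline volume must be positive")
    pct_of_baseline = 100.0 * min(vols) / vols[0]
    if pct_of_baseline > 100.0:
        log.info("CSF rose above baseline (%.1f%%); reduction floored at 0", pct_of_baseline)
        pct_of_baseline = 100.0
    return pct_of_baseline, 100.0 - pct_of_baseline


def compile_cohort(records: Sequence[ScanRecord]) -> CohortTable:
    """Order scans, apply the cohort inclusion rules, derive per-subject metrics.

    Exclusion rules: subjects with fewer than two scans (no follow-up);
    subjects whose only follow-up is more than a week after onset; and
    any scan carrying a QC exclusion flag (e.g. failed registration) is
    dropped before the rules are applied.  Every exclusion is recorded
    with a reason.
    """
    rows = []
    excl: list[dict] = []
    seen: set[tuple[str, float]] = set()
    for r in records:
        key = (r.subject_id, r.time_from_onset_h)
        if key in seen:
            raise EdemascanError(f"duplicate scan for subject {r.subject_id} at {r.time_from_onset_h} h")
        seen.add(key)
        row = {
            "subject_id": r.subject_id,
            "scan_time_h": r.time_from_onset_h,
            "cranial_ml": r.cranial_ml,
            "csf_ml": r.csf_ml,
            "csf_pct": r.csf_pct,
            "infarct_ml": r.infarct_ml,
            "mls_mm": r.mls_mm,
            "ced_grade": r.ced_grade,
            "qc_flags": r.qc_flags,
        }
        if r.qc_flags:
            excl.append({"subject_id": r.subject_id, "scan_time_h": r.time_from_onset_h, "reason": r.qc_flags})
            continue
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS).sort_values(["subject_id", "scan_time_h"]).reset_index(drop=True)

    keep_subjects = []
    subj_rows = []
    for sid, g in df.groupby("subject_id", sort=True):
        if len(g) < 2:
            excl.append({"subject_id": sid, "scan_time_h": np.nan, "reason": "no follow-up scan"})
            continue
        followups = g["scan_time_h"].iloc[1:]
        if followups.min() > FOLLOWUP_LATE_LIMIT_H:
            excl.append(
                {"subject_id": sid, "scan_time_h": np.nan, "reason": "only follow-up more than a week after onset"}
            )
            continue
        keep_subjects.append(sid)
        pct, red = max_csf_reduction(g["csf_ml"].tolist())
        subj_rows.append(
            {
                "subject_id": sid,
                "n_scans": len(g),
                "baseline_csf_ml": float(g["csf_ml"].iloc[0]),
                "min_csf_ml": float(g["csf_ml"].min()),
                "max_reduction_pct": red,
                "pct_of_baseline": pct,
                "baseline_csf_pct": float(g["csf_pct"].iloc[0]),
                "peak_mls_mm": float(g["mls_mm"].max()) if g["mls_mm"].notna().any() else np.nan,
                "max_ced_grade": float(g["ced_grade"].max()) if g["ced_grade"].notna().any() else np.nan,
            }
        )
    scans = df[df["subject_id"].isin(keep_subjects)].reset_index(drop=True)
    subjects = pd.DataFrame(
        subj_rows,
        columns=[
            "subject_id",
            "n_scans",
            "baseline_csf_ml",
            "min_csf_ml",
            "max_reduction_pct",
            "pct_of_baseline",
            "baseline_csf_pct",
            "peak_mls_mm",
            "max_ced_grade",
        ],
    )
    exclusions = pd.DataFrame(excl, columns=["subject_id", "scan_time_h", "reason"])
    for e in excl:
        log.info("excluded %s: %s", e["subject_id"], e["reason"])
    return CohortTable(scans=scans, subjects=subjects, exclusions=exclusions)


def render_overlay(
    vol: CTVolume,
    csf: MaskVolume,
    out_path: str | Path,
    window_center: float = 40.0,
    window_width: float = 80.0,
    columns: int = 6,
) -> Path:
    """Brain-windowed slice montage with the CSF contour in red (PNG).

    Deterministic: identical inputs produce byte-identical files.
    """
    require_same_grid(vol, csf)
    lo = window_center - window_width / 2.0
    gray = np.clip((vol.data - lo) / window_width, 0.0, 1.0)
    contour = csf.data & ~ndimage.binary_erosion(csf.data, np.ones((3, 3, 1), dtype=bool))
    nz = vol.shape[2]
    rows = int(np.ceil(nz / columns))
    nx, ny = vol.shape[0], vol.shape[1]
    canvas = np.zeros((rows * ny, columns * nx, 3), dtype=np.uint8)
    for k in range(nz):
        r, c = divmod(k, columns)
        tile = (gray[:, :, k].T * 255).astype(np.uint8)
        rgb = np.stack([tile] * 3, axis=-1)
        ck = contour[:, :, k].T
        rgb[ck] = (255, 40, 40)
        canvas[r * ny : (r + 1) * ny, c * nx : (c + 1) * nx] = rgb
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, canvas)
    return out_path


def export_cohort_csv(table: CohortTable, out_path: str | Path) -> Path:
    """Write the scan-level table (stable column order; lossless round trip).

    Column dictionary: subject_id; scan_time_h (hours from stroke onset);
    cranial_ml / csf_ml / infarct_ml (compartment volumes); csf_pct (CSF
    as % of cranial volume); mls_mm (manual midline shift); ced_grade
    (manual 0–3 edema grade); qc_flags (empty for analyzed scans).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.scans.to_csv(out_path, index=False, columns=COHORT_COLUMNS, float_format="%.6g")
    return out_path


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise EdemascanError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
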