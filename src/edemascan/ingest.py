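"""DICOM ingestion: series selection, gantry-tilt correction, uniform
slice-thickness resampling, and BIDS-style NIfTI conversion.

CT geometry is always derived from ImagePositionPatient tags, never from
SliceThickness / SpacingBetweenSlices, which scanners report
inconsistently.  A gantry-tilted acquisition stacks naively into a
sheared volume; the correction shifts each slice in-plane by
z_gap·tan(θ) (trigonometry the position tags encode exactly) before
resampling variable inter-slice gaps to the minimum observed gap.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom

from . import __version__
from .core import CTVolume, EdemascanError, HU_MAX, HU_MIN

__all__ = [
    "DicomSeries",
    "load_dicom_dir",
    "compute_slice_spacing",
    "correct_gantry_tilt",
    "resample_uniform_thickness",
    "ingest_series",
    "select_axial_brain_series",
    "convert_to_nifti",
    "DEFAULT_EXCLUSION_LEXICON",
]

POSITION_TOL_MM = 0.01

#: series-description patterns excluded from analysis (scouts, angiography,
#: dose reports ...); configurable because description text varies by site
#: and language.
DEFAULT_EXCLUSION_LEXICON = (
    r"scout",
    r"localizer",
    r"topogram",
    r"angio",
    r"\bcta\b",
    r"perfusion",
    r"dose",
    r"report",
    r"screen.?save",
)


@dataclasses.dataclass
class DicomSlice:
    pixels: np.ndarray  # (nx, ny) HU after rescale
    position: tuple[float, float, float]
    orientation: tuple[float, ...]  # 6 direction cosines (row, col)
    thickness: float
    pixel_spacing: tuple[float, float]  # (col/x, row/y) mm


@dataclasses.dataclass
class DicomSeries:
    """An ordered single-frame CT series plus selection-relevant metadata."""

    slices: list[DicomSlice]
    series_uid: str = ""
    description: str = ""
    derived: bool = False
    kernel: str = ""
    acquisition_time: str = ""
    gantry_tilt_tag: float | None = None
    source_dir: str = ""

    def __post_init__(self) -> None:
        if len(self.slices) < 2:
            raise EdemascanError(f"series {self.series_uid or '?'} has fewer than 2 slices")
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) != 1:
            raise EdemascanError("slices disagree on raster dimensions")
        orients = {tuple(np.round(s.orientation, 6)) for s in self.slices}
        if len(orients) != 1:
            raise EdemascanError("inconsistent orientation cosines across slices")
        normal = self.slice_normal()
        self.slices.sort(key=lambda s: float(np.dot(s.position, normal)))

    def slice_normal(self) -> np.ndarray:
        o = np.asarray(self.slices[0].orientation, dtype=float)
        return np.cross(o[:3], o[3:])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.slices], dtype=float)


def load_dicom_dir(path: str | Path) -> list[DicomSeries]:
    """Read every single-frame CT file under ``path``, grouped by series."""
    path = Path(path)
    groups: dict[str, list[pydicom.Dataset]] = {}
    for f in sorted(path.rglob("*.dcm")):
        ds = pydicom.dcmread(str(f))
        groups.setdefault(str(getattr(ds, "SeriesInstanceUID", "unknown")), []).append(ds)
    out = []
    for uid, dsets in groups.items():
        out.append(_series_from_datasets(uid, dsets, source_dir=str(path)))
    return out


def _series_from_datasets(uid: str, dsets: list[pydicom.Dataset], source_dir: str = "") -> DicomSeries:
    slices = []
    for ds in dsets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + inter
        ps = [float(v) for v in ds.PixelSpacing]  # (row/y, col/x)
        slices.append(
            DicomSlice(
                pixels=hu.T,  # rows=y, cols=x -> index [x, y]
                position=tuple(float(v) for v in ds.ImagePositionPatient),
                orientation=tuple(float(v) for v in ds.ImageOrientationPatient),
                thickness=float(getattr(ds, "SliceThickness", 0.0) or 0.0),
                pixel_spacing=(ps[1], ps[0]),
            )
        )
    ds0 = dsets[0]
    image_type = [str(v).upper() for v in getattr(ds0, "ImageType", [])]
    acq = f"{getattr(ds0, 'AcquisitionDate', '')}T{getattr(ds0, 'AcquisitionTime', '')}"
    tilt = getattr(ds0, "GantryDetectorTilt", None)
    return DicomSeries(
        slices=slices,
        series_uid=uid,
        description=str(getattr(ds0, "SeriesDescription", "")),
        derived="DERIVED" in image_type,
        kernel=str(getattr(ds0, "ConvolutionKernel", "")),
        acquisition_time=acq,
        gantry_tilt_tag=float(tilt) if tilt is not None else None,
        source_dir=source_dir,
    )


# ---------------------------------------------------------------------------
# geometry from position tags


def compute_slice_spacing(series: DicomSeries) -> tuple[list[float], bool]:
    """Euclidean gaps between consecutive slice positions.

    Returns the per-gap distances (mm) and a flag that is true iff the
    maximum deviation from the first gap is below 0.01 mm.  Thickness and
    spacing tags are never consulted.
    """
    pos = series.positions
    gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    for k, g in enumerate(gaps):
        if g < POSITION_TOL_MM:
            raise EdemascanError(f"duplicate slice positions between slices {k} and {k + 1}")
    uniform = bool(np.max(np.abs(gaps - gaps[0])) < POSITION_TOL_MM)
    return [float(g) for g in gaps], uniform


def _tilt_geometry(series: DicomSeries) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-slice stacking-axis positions, in-plane (row-direction) drifts,
    and the tilt angle in degrees, all derived from position tags."""
    o = np.asarray(series.slices[0].orientation, dtype=float)
    row_dir, col_dir = o[:3], o[3:]
    normal = np.cross(row_dir, col_dir)
    pos = series.positions
    rel = pos - pos[0]
    z = rel @ normal
    drift_col = rel @ col_dir  # shear along the column (y) axis
    drift_row = rel @ row_dir
    if np.max(np.abs(drift_row)) > np.max(np.abs(drift_col)) + POSITION_TOL_MM:
        drift = drift_row
    else:
        drift = drift_col
    dz = np.diff(z)
    if np.any(dz <= 0):
        raise EdemascanError("slice positions do not advance monotonically along the normal")
    tilt = float(np.rad2deg(np.arctan2(np.mean(np.abs(np.diff(drift))), np.mean(dz))))
    if np.max(np.abs(drift)) < POSITION_TOL_MM:
        tilt = 0.0
        drift = np.zeros_like(z)
    return z, drift, tilt


def _stack_corrected(series: DicomSeries) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Shear-correct each slice and return (volume array, slice-axis
    positions, tilt degrees, in-plane origin offset mm).  Slices are
    aligned to the frame of the mid-stack slice (the gantry pivots about
    its isocenter, so that frame clips the least anatomy); the offset of
    that frame from slice 0 is reported so the output origin stays
    physically correct.  With zero tilt this is exact pass-through."""
    z, drift, tilt = _tilt_geometry(series)
    mid = int(np.argmin(np.abs(z - z[-1] / 2.0)))
    y_offset = float(drift[mid])
    drift = drift - drift[mid]
    sx, sy = series.slices[0].pixel_spacing
    nx, ny = series.slices[0].pixels.shape
    yi = np.arange(ny, dtype=float)
    arr = np.empty((nx, ny, len(series.slices)), dtype=np.float32)
    for k, sl in enumerate(series.slices):
        shift = drift[k] / sy
        if abs(shift) < 1e-9:
            arr[:, :, k] = sl.pixels
        else:
            # acquired row r sampled physical y-index r + shift, so the
            # corrected value at y comes from acquired row y − shift
            for ix in range(nx):
                arr[ix, :, k] = np.interp(yi - shift, yi, sl.pixels[ix])
    return arr, z, tilt, y_offset


def correct_gantry_tilt(series: DicomSeries) -> CTVolume:
    """Resample a (possibly gantry-tilted) series onto an orthogonal grid.

    The per-slice in-plane shear equals z_gap·tan(θ), read off the
    position tags; an untilted series passes through voxel-identically.
    Requires uniform corrected slice gaps (use :func:`ingest_series` for
    the general case).
    """
    arr, z, _, y_off = _stack_corrected(series)
    dz = np.diff(z)
    if np.max(np.abs(dz - dz[0])) >= POSITION_TOL_MM:
        raise EdemascanError("non-uniform slice gaps; resample_uniform_thickness required")
    return _finalize(series, arr, float(dz[0]), y_off)


def resample_uniform_thickness(series: DicomSeries) -> CTVolume:
    """Interpolate variable inter-slice gaps to the minimum observed gap.

    Values are linearly interpolated along the stacking axis; a series
    that is already uniform passes through bit-identically.  The total
    physical extent is preserved.
    """
    arr, z, _, y_off = _stack_corrected(series)
    return _resample_z(series, arr, z, y_off)


def _resample_z(series: DicomSeries, arr: np.ndarray, z: np.ndarray, y_off: float = 0.0) -> CTVolume:
    dz = np.diff(z)
    if np.max(np.abs(dz - dz[0])) < POSITION_TOL_MM:
        return _finalize(series, arr, float(dz[0]), y_off)
    target = float(np.min(dz))
    n_out = int(np.floor((z[-1] - z[0]) / target)) + 1
    z_out = z[0] + target * np.arange(n_out)
    idx = np.searchsorted(z, z_out, side="right") - 1
    idx = np.clip(idx, 0, len(z) - 2)
    w = (z_out - z[idx]) / (z[idx + 1] - z[idx])
    out = (1.0 - w) * arr[:, :, idx] + w * arr[:, :, idx + 1]
    return _finalize(series, out.astype(np.float32), target, y_off)


def ingest_series(series: DicomSeries) -> CTVolume:
    """Full geometric ingestion: tilt correction then uniform resampling."""
    arr, z, _, y_off = _stack_corrected(series)
    return _resample_z(series, arr, z, y_off)


def _finalize(series: DicomSeries, arr: np.ndarray, dz: float, y_off: float = 0.0) -> CTVolume:
    sx, sy = series.slices[0].pixel_spacing
    pos0 = series.slices[0].position
    col_dir = np.asarray(series.slices[0].orientation[3:], dtype=float)
    origin = tuple(np.asarray(pos0, dtype=float) + y_off * col_dir)
    vol = CTVolume(
        np.clip(arr, HU_MIN, HU_MAX),
        spacing=(sx, sy, dz),
        origin=origin,
        acquisition_time=series.acquisition_time or None,
    )
    return vol


# ---------------------------------------------------------------------------
# series selection


def select_axial_brain_series(
    session: Sequence[DicomSeries],
    exclusion_lexicon: Sequence[str] = DEFAULT_EXCLUSION_LEXICON,
) -> DicomSeries:
    """Pick the analyzable axial soft-tissue brain series from a session.

    Excludes derived reconstructions, bone-kernel series, non-axial
    stacks, and descriptions matching the exclusion lexicon; among the
    survivors prefers the series with the most slices, breaking ties by
    earliest acquisition time.
    """
    if len(session) == 0:
        raise EdemascanError("empty session")
    reasons: dict[str, str] = {}
    survivors = []
    for s in session:
        label = s.series_uid or s.description or "series"
        if s.derived:
            reasons[label] = "derived image type"
            continue
        if "BONE" in s.kernel.upper():
            reasons[label] = f"bone reconstruction kernel ({s.kernel})"
            continue
        desc = s.description.lower()
        hit = next((p for p in exclusion_lexicon if re.search(p, desc)), None)
        if hit is not None:
            reasons[label] = f"description matches exclusion pattern {hit!r}"
            continue
        normal = s.slice_normal()
        if abs(normal[2]) < 0.9:
            reasons[label] = "not an axial stack"
            continue
        survivors.append(s)
    if not survivors:
        detail = "; ".join(f"{k}: {v}" for k, v in reasons.items())
        raise EdemascanError(f"no analyzable axial brain series in session ({detail})")
    survivors.sort(key=lambda s: (-len(s.slices), s.acquisition_time))
    return survivors[0]


# ---------------------------------------------------------------------------
# NIfTI + sidecar


def convert_to_nifti(
    vol: CTVolume,
    subject_id: str,
    out_dir: str | Path,
    sidecar_extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write ``sub-<id>_ses-<timestamp>_ct.nii.gz`` plus a BIDS-style JSON
    sidecar recording conversion provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = re.sub(r"[^0-9T]", "", vol.acquisition_time or "unknown") or "unknown"
    stem = f"sub-{subject_id}_ses-{stamp}_ct"
    nii_path = out_dir / f"{stem}.nii.gz"
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(nii_path))
    sidecar = {
        "Modality": "CT",
        "ConversionSoftware": "edemascan",
        "ConversionSoftwareVersion": __version__,
        "AcquisitionDateTime": vol.acquisition_time,
        "VoxelSizeMm": list(vol.spacing),
    }
    if sidecar_extra:
        sidecar.update(sidecar_extra)
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return nii_path, json_path


def ingest_and_convert(
    dicom_dir: str | Path,
    subject_id: str,
    out_dir: str | Path,
    exclusion_lexicon: Sequence[str] = DEFAULT_EXCLUSION_LEXICON,
) -> tuple[Path, Path]:
    """Directory-level convenience: select, ingest, convert one session."""
    session = load_dicom_dir(dicom_dir)
    series = select_axial_brain_series(session, exclusion_lexicon)
    gaps, uniform = compute_slice_spacing(series)
    _, _, tilt = _tilt_geometry(series)
    vol = ingest_series(series)
    extra = {
        "GantryTilt": tilt,
        "GantryTiltTag": series.gantry_tilt_tag,
        "SliceGapsMm": [round(g, 4) for g in gaps],
        "UniformSpacing": uniform,
        "SeriesDescription": series.description,
        "SourceDirectory": str(dicom_dir),
    }
    return convert_to_nifti(vol, subject_id, out_dir, sidecar_extra=extra)
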