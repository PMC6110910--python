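"""Core raster containers shared by every pipeline stage.

A :class:`CTVolume` is a 3-D Hounsfield-unit image with physical voxel
geometry; a :class:`MaskVolume` is a binary labeling aligned voxel-for-voxel
to some CTVolume.  Arrays are indexed ``[x, y, z]`` with the slice (axial)
axis last; orientation is kept axis-aligned (identity direction cosines)
throughout — acquisition obliquity is resolved at ingest, never propagated.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1100.0
HU_MAX = 4000.0


class EdemascanError(Exception):
    """Base class for pipeline errors."""


class GeometryError(EdemascanError):
    """A parametric region does not fit its containing grid or compartment."""


class DegenerateInputError(EdemascanError):
    """Input lacks the variation an operation requires (e.g. constant image)."""


class RegistrationFailure(EdemascanError):
    """Alignment between two scans could not be established."""


class GridMismatchError(EdemascanError):
    """Two rasters expected on the same voxel grid differ in shape/spacing."""


@dataclasses.dataclass
class CTVolume:
    """3-D CT image in Hounsfield units with voxel geometry.

    Parameters
    ----------
    data:
        float array of shape ``(nx, ny, nz)``; HU values.
    spacing:
        voxel edge lengths in mm per axis (strictly positive, uniform
        along each axis).
    origin:
        physical position (mm) of voxel ``(0, 0, 0)``.
    acquisition_time:
        optional ISO-8601 timestamp carried through from the scanner.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    acquisition_time: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing, self.origin, self.acquisition_time)


@dataclasses.dataclass
class MaskVolume:
    """Binary voxel labeling aligned to a CTVolume grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"MaskVolume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.count() * float(np.prod(self.spacing)) / 1000.0

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.data.copy(), self.spacing, self.origin)


def same_grid(a: CTVolume | MaskVolume, b: CTVolume | MaskVolume, atol: float = 1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing, atol=atol)


def require_same_grid(a: CTVolume | MaskVolume, b: CTVolume | MaskVolume) -> None:
    if not same_grid(a, b):
        raise GridMismatchError(
            f"grids differ: shape {a.shape} / spacing {a.spacing} vs shape {b.shape} / spacing {b.spacing}"
        )


def dice(a: MaskVolume | np.ndarray, b: MaskVolume | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 for two empty masks."""
    aa = a.data if isinstance(a, MaskVolume) else np.asarray(a, dtype=bool)
    bb = b.data if isinstance(b, MaskVolume) else np.asarray(b, dtype=bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(aa, bb).sum() / denom)


def resample_like(
    src: CTVolume | MaskVolume,
    ref: CTVolume | MaskVolume,
    order: int = 1,
    cval: float = 0.0,
) -> CTVolume | MaskVolume:
    """Resample ``src`` onto the voxel grid of ``ref`` using the physical
    geometry (origin + spacing) of both rasters; axis-aligned only."""
    from scipy import ndimage

    src_data = src.data.astype(np.float32)
    coords = []
    for ax in range(3):
        idx = np.arange(ref.shape[ax], dtype=float)
        phys = ref.origin[ax] + idx * ref.spacing[ax]
        coords.append((phys - src.origin[ax]) / src.spacing[ax])
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(src_data, grid, order=order, mode="constant", cval=cval, prefilter=False)
    if isinstance(src, MaskVolume):
        return MaskVolume(out > 0.5, ref.spacing, ref.origin)
    return CTVolume(out, ref.spacing, ref.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_nifti(vol: CTVolume | MaskVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data.astype(np.uint8) if isinstance(vol, MaskVolume) else vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine=_affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def _affine(vol: CTVolume | MaskVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def load_ct_nifti(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return CTVolume(data, zooms, origin)


def load_mask_nifti(path: str | Path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return MaskVolume(data, zooms, origin)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
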