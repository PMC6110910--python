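"""Skull stripping by k-means intensity clustering and morphology.

On CT, air/external (~−1000 HU), soft tissue including brain and CSF
(~0–60 HU) and bone (≫100 HU) form three well-separated intensity modes,
so scalar k-means with k = 3 is equivalent to optimal midpoint
thresholding.  The intracranial mask is the soft-tissue class after hole
filling (re-capturing CSF inside the skull), suppression of tissue
connected to the volume border through non-bone paths (scalp, face), and
retention of the largest connected component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import CTVolume, DegenerateInputError, MaskVolume

__all__ = ["TissueLabeling", "kmeans_tissue_clusters", "extract_intracranial_mask", "skull_strip"]

EXTERNAL, BRAIN_SOFT, SKULL = 0, 1, 2


@dataclasses.dataclass
class TissueLabeling:
    """Per-voxel tissue class (0 external, 1 soft tissue, 2 bone) and the
    class mean HU, strictly ordered external < brain_soft < skull."""

    labels: np.ndarray
    centers: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError(f"class centers must be strictly increasing, got {self.centers}")


def kmeans_tissue_clusters(vol: CTVolume, k: int = 3, seed: int = 0) -> TissueLabeling:
    """Lloyd's algorithm (k-means++ seeding) on scalar HU.

    Classes are relabeled by ascending center so that label 0 is always
    external/air, 1 soft tissue and 2 bone.
    """
    values = vol.data.reshape(-1, 1).astype(np.float64)
    if len(np.unique(values)) < k:
        raise DegenerateInputError(f"need at least {k} distinct HU values for {k}-means")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100, tol=1e-8, random_state=seed)
    raw = km.fit_predict(values)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=np.uint8)
    relabel[order] = np.arange(k, dtype=np.uint8)
    labels = relabel[raw].reshape(vol.shape)
    centers = tuple(float(c) for c in np.sort(km.cluster_centers_.ravel()))
    return TissueLabeling(labels=labels, centers=centers)


def extract_intracranial_mask(labeling: TissueLabeling, vol: CTVolume) -> MaskVolume:
    """Reduce a tissue labeling to the intracranial-content mask.

    Steps: soft-tissue class → slice-wise then 3-D hole filling (CSF,
    darker than the soft-tissue center, is re-captured inside the skull)
    → removal of voxels reachable from the volume border through
    non-bone paths (6-connectivity, conservative against leakage through
    thin skull gaps) → largest 26-connected component.
    """
    soft = labeling.labels == BRAIN_SOFT
    if not soft.any():
        raise DegenerateInputError("soft-tissue class is empty; cannot extract intracranial mask")
    mask = soft.copy()
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    mask = ndimage.binary_fill_holes(mask)

    non_skull = labeling.labels != SKULL
    external = _border_connected(non_skull)
    mask &= ~external

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise DegenerateInputError(
            "no intracranial component remains: brain reaches the volume border (no closed skull)"
        )
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    mask = comp == (1 + int(np.argmax(sizes)))
    return MaskVolume(mask, vol.spacing, vol.origin)


def _border_connected(region: np.ndarray) -> np.ndarray:
    """Voxels of ``region`` reachable from the volume border (6-conn)."""
    comp, n = ndimage.label(region)  # default structure = 6-connectivity
    if n == 0:
        return np.zeros_like(region)
    border_labels = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(comp, sl, axis=ax)
            border_labels |= set(np.unique(face[face > 0]).tolist())
    out = np.isin(comp, sorted(border_labels))
    return out


def skull_strip(vol: CTVolume, seed: int = 0) -> tuple[MaskVolume, TissueLabeling]:
    """Convenience: cluster then extract, returning mask and labeling."""
    labeling = kmeans_tissue_clusters(vol, k=3, seed=seed)
    return extract_intracranial_mask(labeling, vol), labeling
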