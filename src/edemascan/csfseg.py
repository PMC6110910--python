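"""CSF segmentation: random-forest voxel classification on Haar-like
features, active-contour refinement, and infarct-mask cleaning.

The classifier works inside the cranial mask only.  Features are
differences of axis-aligned box means computed in O(1) per box from a
3-D summed-area table; boxes are 2-D (in-plane) by default because CT
slices are several times thicker than in-plane pixels.  The intensity
window that separates CSF (~8 HU) from brain (~32 HU) also admits
infarcted tissue (~18 HU), which is why a learned classifier with
spatial context beats plain HU thresholding — the threshold baseline is
provided for exactly that comparison.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from skimage.segmentation import morphological_chan_vese
from sklearn.ensemble import RandomForestClassifier

from . import __version__
from .core import CTVolume, DegenerateInputError, MaskVolume, require_same_grid

__all__ = [
    "HaarFeatureSpec",
    "CsfClassifier",
    "integral_volume",
    "box_sum",
    "haar_features",
    "train_csf_classifier",
    "predict_csf",
    "threshold_baseline_segment",
    "refine_active_contour",
    "clean_with_infarct_mask",
    "save_classifier",
    "load_classifier",
]


@dataclasses.dataclass(frozen=True)
class HaarFeatureSpec:
    """Haar-like feature bank: per scale, a center box mean, a
    center−surround difference, and paired-box differences along each
    axis; optional raw channels (HU, 3×3×1 local mean and SD)."""

    scales: tuple[int, ...] = (1, 2, 4, 8)
    patterns: tuple[str, ...] = ("center", "center_surround", "left_right", "up_down", "front_back")
    include_raw: bool = True
    use_3d: bool = False

    def __post_init__(self) -> None:
        if len(self.patterns) == 0:
            raise ValueError("pattern set must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        bad = set(self.patterns) - {"center", "center_surround", "left_right", "up_down", "front_back"}
        if bad:
            raise ValueError(f"unknown patterns: {sorted(bad)}")

    @property
    def n_features(self) -> int:
        return len(self.scales) * len(self.patterns) + (3 if self.include_raw else 0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HaarFeatureSpec":
        return cls(
            scales=tuple(d["scales"]),
            patterns=tuple(d["patterns"]),
            include_raw=bool(d["include_raw"]),
            use_3d=bool(d["use_3d"]),
        )


def integral_volume(vol: CTVolume | np.ndarray) -> np.ndarray:
    """3-D summed-area table with a zero face prepended on each axis, so
    any axis-aligned box sum is 8 corner lookups."""
    data = vol.data if isinstance(vol, CTVolume) else np.asarray(vol)
    if not np.all(np.isfinite(data)):
        raise ValueError("integral volume requires finite voxels")
    iv = np.zeros(tuple(s + 1 for s in data.shape), dtype=np.float64)
    iv[1:, 1:, 1:] = data.astype(np.float64).cumsum(0).cumsum(1).cumsum(2)
    return iv


def box_sum(iv: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sum of voxels in inclusive boxes [lo, hi] via corner lookups.

    ``lo``/``hi`` are integer arrays of shape (N, 3), already inside the
    volume bounds.
    """
    x0, y0, z0 = lo[:, 0], lo[:, 1], lo[:, 2]
    x1, y1, z1 = hi[:, 0] + 1, hi[:, 1] + 1, hi[:, 2] + 1
    return (
        iv[x1, y1, z1]
        - iv[x0, y1, z1]
        - iv[x1, y0, z1]
        - iv[x1, y1, z0]
        + iv[x0, y0, z1]
        + iv[x0, y1, z0]
        + iv[x1, y0, z0]
        - iv[x0, y0, z0]
    )


def _box_mean(iv: np.ndarray, shape: tuple[int, ...], coords: np.ndarray, lo_off: np.ndarray, hi_off: np.ndarray) -> np.ndarray:
    """Mean over boxes coords+lo_off .. coords+hi_off, clipped to bounds
    (clipped boxes renormalized by their actual voxel count)."""
    dims = np.asarray(shape)
    lo = np.clip(coords + lo_off, 0, dims - 1)
    hi = np.clip(coords + hi_off, 0, dims - 1)
    counts = np.prod(hi - lo + 1, axis=1)
    return box_sum(iv, lo, hi) / counts


def haar_features(
    vol: CTVolume,
    coords: np.ndarray,
    spec: HaarFeatureSpec = HaarFeatureSpec(),
    iv: np.ndarray | None = None,
    iv2: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix (N, n_features) at integer voxel ``coords`` (N, 3).

    For scale s the center box has half-width s in-plane (and along the
    slice axis too when ``use_3d``); paired boxes are the adjacent
    non-overlapping boxes shifted by 2s+1 along the pattern axis (the
    front−back pair always uses single-slice boxes shifted by one slice).
    All boxes are clipped at the volume bounds and renormalized.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
    if iv is None:
        iv = integral_volume(vol)
    feats = np.empty((coords.shape[0], spec.n_features), dtype=np.float32)
    col = 0
    for s in spec.scales:
        sz = s if spec.use_3d else 0
        c_lo, c_hi = np.array([-s, -s, -sz]), np.array([s, s, sz])
        center = _box_mean(iv, vol.shape, coords, c_lo, c_hi)
        for pat in spec.patterns:
            if pat == "center":
                f = center
            elif pat == "center_surround":
                s_lo, s_hi = np.array([-2 * s - 1, -2 * s - 1, -sz]), np.array([2 * s + 1, 2 * s + 1, sz])
                lo = np.clip(coords + s_lo, 0, np.asarray(vol.shape) - 1)
                hi = np.clip(coords + s_hi, 0, np.asarray(vol.shape) - 1)
                big_sum = box_sum(iv, lo, hi)
                big_n = np.prod(hi - lo + 1, axis=1)
                lo_c = np.clip(coords + c_lo, 0, np.asarray(vol.shape) - 1)
                hi_c = np.clip(coords + c_hi, 0, np.asarray(vol.shape) - 1)
                c_sum = box_sum(iv, lo_c, hi_c)
                c_n = np.prod(hi_c - lo_c + 1, axis=1)
                ring_n = np.maximum(big_n - c_n, 1)
                f = center - (big_sum - c_sum) / ring_n
            elif pat in ("left_right", "up_down"):
                ax = 0 if pat == "left_right" else 1
                shift = np.zeros(3, dtype=np.int64)
                shift[ax] = 2 * s + 1
                a = _box_mean(iv, vol.shape, coords, c_lo - shift, c_hi - shift)
                b = _box_mean(iv, vol.shape, coords, c_lo + shift, c_hi + shift)
                f = a - b
            else:  # front_back: single-slice boxes one slice away
                shift = np.array([0, 0, max(sz, 1) + sz])
                a = _box_mean(iv, vol.shape, coords, c_lo - shift, c_hi - shift)
                b = _box_mean(iv, vol.shape, coords, c_lo + shift, c_hi + shift)
                f = a - b
            feats[:, col] = f
            col += 1
    if spec.include_raw:
        raw = vol.data[coords[:, 0], coords[:, 1], coords[:, 2]]
        if iv2 is None:
            iv2 = integral_volume(vol.data.astype(np.float64) ** 2)
        lo, hi = np.array([-1, -1, 0]), np.array([1, 1, 0])
        local_mean = _box_mean(iv, vol.shape, coords, lo, hi)
        local_sq = _box_mean(iv2, vol.shape, coords, lo, hi)
        local_sd = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
        feats[:, col] = raw
        feats[:, col + 1] = local_mean
        feats[:, col + 2] = local_sd
    return feats


@dataclasses.dataclass
class CsfClassifier:
    """Trained CSF voxel classifier: forest + feature spec + provenance."""

    forest: RandomForestClassifier
    feature_spec: HaarFeatureSpec
    provenance: dict

    @property
    def oob_accuracy(self) -> float | None:
        return self.provenance.get("oob_accuracy")


def train_csf_classifier(
    training: Sequence[tuple[CTVolume, MaskVolume, MaskVolume]],
    spec: HaarFeatureSpec = HaarFeatureSpec(),
    n_trees: int = 100,
    max_depth: int = 20,
    per_class_cap: int = 4000,
    seed: int = 0,
) -> CsfClassifier:
    """Fit the random forest on (CT, cranial mask, CSF truth) triples.

    Voxels are sampled inside each cranial mask, balanced between CSF and
    non-CSF up to ``per_class_cap`` per volume; out-of-bag accuracy is
    recorded in the provenance.
    """
    if len(training) == 0:
        raise ValueError("need at least one training volume")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for vol, cranial, csf_truth in training:
        require_same_grid(vol, cranial)
        require_same_grid(vol, csf_truth)
        if not csf_truth.data.any():
            raise DegenerateInputError("CSF truth mask is empty")
        inside = cranial.data
        pos = np.argwhere(inside & csf_truth.data)
        neg = np.argwhere(inside & ~csf_truth.data)
        n = min(per_class_cap, len(pos), len(neg))
        pos = pos[rng.choice(len(pos), size=n, replace=False)]
        neg = neg[rng.choice(len(neg), size=n, replace=False)]
        coords = np.vstack([pos, neg])
        X_parts.append(haar_features(vol, coords, spec))
        y_parts.append(np.concatenate([np.ones(n), np.zeros(n)]))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    provenance = {
        "software_version": __version__,
        "n_training_volumes": len(training),
        "n_samples": int(len(y)),
        "n_trees": n_trees,
        "max_depth": max_depth,
        "per_class_cap": per_class_cap,
        "seed": seed,
        "oob_accuracy": float(forest.oob_score_),
        "feature_spec": spec.to_dict(),
    }
    return CsfClassifier(forest=forest, feature_spec=spec, provenance=provenance)


def predict_csf(
    vol: CTVolume,
    cranial: MaskVolume,
    clf: CsfClassifier,
    threshold: float = 0.5,
    spec: HaarFeatureSpec | None = None,
) -> tuple[MaskVolume, np.ndarray]:
    """Per-voxel CSF probability inside the cranial mask, binarized.

    Returns the binary mask and the probability volume (zero outside the
    cranial mask — no voxel outside it is ever labeled CSF).
    """
    require_same_grid(vol, cranial)
    if spec is not None and spec != clf.feature_spec:
        raise ValueError("feature spec mismatch between caller and classifier")
    coords = np.argwhere(cranial.data)
    prob = np.zeros(vol.shape, dtype=np.float32)
    if len(coords):
        X = haar_features(vol, coords, clf.feature_spec)
        p = clf.forest.predict_proba(X)[:, list(clf.forest.classes_).index(1.0)]
        prob[coords[:, 0], coords[:, 1], coords[:, 2]] = p
    mask = (prob > threshold) & cranial.data
    return MaskVolume(mask, vol.spacing, vol.origin), prob


def threshold_baseline_segment(
    vol: CTVolume, cranial: MaskVolume, hu_window: tuple[float, float] = (0.0, 15.0)
) -> MaskVolume:
    """Plain HU-window CSF segmentation (the baseline the forest must
    beat): cranial voxels with lo ≤ HU ≤ hi."""
    lo, hi = hu_window
    if lo >= hi:
        raise ValueError(f"need lo < hi, got {hu_window}")
    mask = cranial.data & (vol.data >= lo) & (vol.data <= hi)
    return MaskVolume(mask, vol.spacing, vol.origin)


def refine_active_contour(
    vol: CTVolume,
    init: MaskVolume,
    cranial: MaskVolume | None = None,
    iterations: int = 10,
    smoothing: int = 1,
) -> MaskVolume:
    """Morphological Chan–Vese (two-phase, region-based) refinement.

    The contour evolves from ``init`` for a fixed iteration budget; the
    result is constrained to the cranial mask when one is given.
    """
    if not init.data.any():
        raise DegenerateInputError("active-contour initialization is empty")
    require_same_grid(vol, init)
    work = vol.data.astype(np.float32)
    if cranial is not None:
        # restrict the evolution to the cranial compartment: non-cranial
        # voxels (air, skull) take the brain-tissue median so they behave
        # as background phase instead of skewing the outside mean
        inside = cranial.data & ~init.data
        fill = np.float32(np.median(work[inside])) if inside.any() else np.float32(35.0)
        work = np.where(cranial.data, work, fill)
    # slice-wise 2-D evolution: CT slices are several times thicker than
    # in-plane pixels, so 3-D curvature operators would erode thin fluid
    # sheets spanning one or two slices
    out = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[2]):
        init_z = init.data[:, :, z]
        if not init_z.any():
            continue
        out[:, :, z] = morphological_chan_vese(
            work[:, :, z], num_iter=iterations, init_level_set=init_z.astype(np.int8), smoothing=smoothing
        ).astype(bool)
    if cranial is not None:
        out &= cranial.data
    return MaskVolume(out, vol.spacing, vol.origin)


def clean_with_infarct_mask(csf: MaskVolume, infarct: MaskVolume) -> MaskVolume:
    """Remove (manually outlined) infarct hypodensity from the CSF mask."""
    require_same_grid(csf, infarct)
    return MaskVolume(csf.data & ~infarct.data, csf.spacing, csf.origin)


# ---------------------------------------------------------------------------
# classifier bundle serialization


def save_classifier(clf: CsfClassifier, bundle_dir: str | Path) -> Path:
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(clf.forest, bundle_dir / "forest.joblib")
    (bundle_dir / "provenance.json").write_text(json.dumps(clf.provenance, indent=2, sort_keys=True) + "\n")
    return bundle_dir


def load_classifier(bundle_dir: str | Path) -> CsfClassifier:
    bundle_dir = Path(bundle_dir)
    forest = joblib.load(bundle_dir / "forest.joblib")
    provenance = json.loads((bundle_dir / "provenance.json").read_text())
    spec = HaarFeatureSpec.from_dict(provenance["feature_spec"])
    return CsfClassifier(forest=forest, feature_spec=spec, provenance=provenance)
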