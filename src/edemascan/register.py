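"""Rigid/affine registration, multi-atlas cranial-perimeter fusion, and
longitudinal mask propagation with QC.

The cranial analysis region is defined on the baseline scan by majority
vote over an atlas of template scans with outlined cranial perimeters
(a voxel is kept iff it is inside the warped mask of strictly more than
half the surviving templates), then propagated to each follow-up by
intra-subject registration.  Registration itself is a 3-level
multi-resolution optimization of normalized cross-correlation over rigid
(then affine) parameters; masks are always resampled nearest-neighbor so
they stay binary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import SimpleITK as sitk

from .core import CTVolume, MaskVolume, RegistrationFailure

__all__ = [
    "AtlasSet",
    "RigidAffineTransform",
    "register_volumes",
    "multi_atlas_cranial_mask",
    "propagate_mask_to_followup",
    "registration_qc",
    "rigid_error",
]

QC_RATIO_TOLERANCE = 0.10
MIN_NCC_SCORE = 0.3  # |NCC| below this flags non-convergence (no structure)


@dataclasses.dataclass
class AtlasSet:
    """Template CT volumes paired with their cranial-perimeter masks."""

    templates: list[tuple[CTVolume, MaskVolume]]

    def __post_init__(self) -> None:
        if len(self.templates) < 3:
            raise ValueError("atlas needs at least 3 templates for a meaningful vote")
        if len(self.templates) % 2 == 0:
            warnings.warn("even atlas size: strict-majority votes can discard exact ties", stacklevel=2)

    def __len__(self) -> int:
        return len(self.templates)


@dataclasses.dataclass
class RigidAffineTransform:
    """4×4 homogeneous map from fixed physical coordinates to moving."""

    matrix: np.ndarray
    score: float  # |NCC| achieved
    converged: bool
    mode: str = "rigid"

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (self.matrix[:3, :3] @ pts.T).T + self.matrix[:3, 3]


def _to_sitk(vol: CTVolume | MaskVolume, dtype=sitk.sitkFloat32) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(vol.data.astype(np.float32), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img = sitk.Cast(img, dtype)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _from_sitk_mask(img: sitk.Image, like: CTVolume | MaskVolume) -> MaskVolume:
    arr = sitk.GetArrayFromImage(img)
    return MaskVolume(np.transpose(arr, (2, 1, 0)) > 0.5, like.spacing, like.origin)


def _matrix_from_transform(tf: sitk.Transform) -> np.ndarray:
    tf = tf.Downcast() if hasattr(tf, "Downcast") else tf
    A = np.asarray(tf.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tf.GetCenter(), dtype=float)
    t = np.asarray(tf.GetTranslation(), dtype=float)
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = c + t - A @ c
    return m


def register_volumes(
    moving: CTVolume,
    fixed: CTVolume,
    mode: str = "rigid",
    seed: int = 0,
    min_score: float = MIN_NCC_SCORE,
    iterations: int = 200,
    polish: bool = True,
) -> RigidAffineTransform:
    """Estimate the transform mapping fixed-scan points onto the moving scan.

    Three-level multi-resolution (shrink 4/2/1) regular-step gradient
    descent on the negative normalized cross-correlation seeds a
    full-resolution Powell refinement of the six rigid parameters, which
    recovers sub-voxel translation and sub-degree rotation; for
    ``mode='affine'`` the refined rigid solution then seeds an affine
    stage.  Full-image metric sampling keeps the optimization
    deterministic; ``seed`` is part of the contract for forward
    compatibility with sampled metrics.

    Raises :class:`RegistrationFailure` when the achieved |NCC| stays
    below ``min_score`` (nothing to align, e.g. a structureless image).
    """
    if mode not in ("rigid", "affine"):
        raise ValueError(f"mode must be 'rigid' or 'affine', got {mode!r}")
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    euler, score = _run_stage(f_img, m_img, sitk.Euler3DTransform(initial), iterations)
    matrix = _matrix_from_transform(euler)
    score = float(np.sqrt(abs(score)))  # Correlation metric is -NCC²-scale
    if polish:
        matrix, score = _polish_rigid(moving, fixed, matrix)
    if mode == "affine":
        aff = sitk.AffineTransform(3)
        center = tuple(np.asarray(fixed.origin) + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing) / 2.0)
        aff.SetCenter(center)
        aff.SetMatrix(tuple(matrix[:3, :3].ravel()))
        c = np.asarray(center)
        aff.SetTranslation(tuple(matrix[:3, 3] + matrix[:3, :3] @ c - c))
        aff, _ = _run_stage(f_img, m_img, aff, iterations)
        aff_matrix = _matrix_from_transform(aff)
        # score both candidates with the same overlap-NCC evaluator and keep
        # the better one: a diverged affine stage must not discard a good
        # rigid solution
        rigid_score = _overlap_ncc(moving, fixed, matrix)
        aff_score = _overlap_ncc(moving, fixed, aff_matrix)
        if aff_score >= rigid_score:
            matrix, score = aff_matrix, aff_score
        else:
            matrix, score = matrix, rigid_score
    result = RigidAffineTransform(
        matrix=matrix,
        score=score,
        converged=bool(score >= min_score),
        mode=mode,
    )
    if not result.converged:
        raise RegistrationFailure(
            f"registration did not converge: |NCC| = {result.score:.3f} < {min_score}"
        )
    return result


def _resample_to_fixed(moving: CTVolume, fixed: CTVolume, matrix: np.ndarray, cval: float) -> np.ndarray:
    """Pull moving-image HU onto the fixed grid under a fixed→moving map."""
    from scipy import ndimage as ndi

    s_f = np.asarray(fixed.spacing)
    s_m = np.asarray(moving.spacing)
    A = matrix[:3, :3] * s_f[np.newaxis, :] / s_m[:, np.newaxis]
    off = (matrix[:3, :3] @ np.asarray(fixed.origin) + matrix[:3, 3] - np.asarray(moving.origin)) / s_m
    return ndi.affine_transform(
        moving.data.astype(np.float32), A, offset=off, output_shape=fixed.shape,
        order=1, mode="constant", cval=cval, prefilter=False,
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _overlap_ncc(moving: CTVolume, fixed: CTVolume, matrix: np.ndarray) -> float:
    """|NCC| over the in-FOV overlap under a candidate fixed→moving map."""
    warped = _resample_to_fixed(moving, fixed, matrix, np.nan)
    valid = np.isfinite(warped)
    if valid.mean() < 0.25:
        return 0.0
    return abs(_ncc(warped[valid], fixed.data[valid]))


def _polish_rigid(moving: CTVolume, fixed: CTVolume, matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Full-resolution Powell refinement of the 6 rigid parameters."""
    from scipy import optimize
    from scipy.spatial.transform import Rotation

    from .phantom import RigidMotion

    center = tuple(np.asarray(fixed.origin) + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing) / 2.0)
    Rm = matrix[:3, :3]
    rz, ry, rx = np.rad2deg(Rotation.from_matrix(Rm).as_euler("ZYX"))
    c = np.asarray(center)
    t_c = matrix[:3, 3] + Rm @ c - c
    p0 = np.array([rx, ry, rz, *t_c])

    def cost(p: np.ndarray) -> float:
        m = RigidMotion(tuple(p[3:]), tuple(p[:3]), center).as_matrix()
        warped = _resample_to_fixed(moving, fixed, m, np.nan)
        valid = np.isfinite(warped)
        # NCC over the in-FOV overlap only: constant padding must not
        # masquerade as structure, and sliding out of overlap must not pay
        if valid.mean() < 0.25:
            return 0.0
        return -_ncc(warped[valid], fixed.data[valid])

    res = optimize.minimize(cost, p0, method="Powell", options=dict(xtol=2e-3, ftol=1e-6, maxfev=300))
    best = res.x if res.fun <= cost(p0) else p0
    m = RigidMotion(tuple(best[3:]), tuple(best[:3]), center).as_matrix()
    return m, float(-cost(best))


def _run_stage(f_img: sitk.Image, m_img: sitk.Image, transform: sitk.Transform, iterations: int):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=iterations, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(transform, inPlace=True)
    reg.Execute(f_img, m_img)
    return transform, reg.GetMetricValue()  # Correlation metric: -NCC²-like, ≤ 0


def _resample_mask(mask: MaskVolume, reference: CTVolume, matrix: np.ndarray) -> MaskVolume:
    ref_img = _to_sitk(reference)
    mask_img = _to_sitk(mask, dtype=sitk.sitkFloat32)
    tf = sitk.AffineTransform(3)
    tf.SetMatrix(tuple(matrix[:3, :3].ravel()))
    tf.SetTranslation(tuple(matrix[:3, 3]))
    out = sitk.Resample(mask_img, ref_img, tf, sitk.sitkNearestNeighbor, 0.0)
    return _from_sitk_mask(out, reference)


def multi_atlas_cranial_mask(
    baseline: CTVolume,
    atlas: AtlasSet,
    seed: int = 0,
    intracranial: MaskVolume | None = None,
) -> MaskVolume:
    """Strict-majority fusion of atlas cranial-perimeter masks.

    Each template is registered to the baseline (affine), its mask warped
    nearest-neighbor, and a voxel is included iff it lies inside strictly
    more than half of the successfully warped masks.  Templates whose
    registration fails are dropped with a warning and the vote threshold
    is recomputed on the survivors; more than half failing is a hard
    failure.  The fused mask is intersected with the skull-strip
    intracranial mask when one is supplied.
    """
    n = len(atlas)
    votes = np.zeros(baseline.shape, dtype=np.int32)
    n_ok = 0
    for idx, (tpl_vol, tpl_mask) in enumerate(atlas.templates):
        try:
            tf = register_volumes(moving=tpl_vol, fixed=baseline, mode="affine", seed=seed + idx)
        except RegistrationFailure as exc:
            warnings.warn(f"atlas template {idx} dropped: {exc}", stacklevel=2)
            continue
        votes += _resample_mask(tpl_mask, baseline, tf.matrix).data
        n_ok += 1
    if n_ok <= n / 2:
        raise RegistrationFailure(f"multi-atlas fusion failed: only {n_ok}/{n} templates registered")
    fused = majority_vote(votes, n_ok)
    if intracranial is not None:
        fused &= intracranial.data
    return MaskVolume(fused, baseline.spacing, baseline.origin)


def majority_vote(votes: np.ndarray, n_templates: int) -> np.ndarray:
    """Strict majority: included iff matched in more than half the templates."""
    return votes > n_templates / 2.0


def propagate_mask_to_followup(
    baseline: CTVolume,
    cranial: MaskVolume,
    followup: CTVolume,
    seed: int = 0,
    mode: str = "rigid",
) -> MaskVolume:
    """Carry the baseline cranial mask onto a follow-up scan's grid.

    The baseline→follow-up transform is estimated on the images and the
    mask resampled nearest-neighbor; voxels of the follow-up outside the
    propagated mask are excluded from all downstream volumetrics.  A
    :class:`RegistrationFailure` propagates so the caller can flag and
    exclude the scan.
    """
    tf = register_volumes(moving=baseline, fixed=followup, mode=mode, seed=seed)
    return _resample_mask(cranial, followup, tf.matrix)


def registration_qc(baseline_vol_ml: float, followup_vol_ml: float) -> bool:
    """Pass iff the follow-up/baseline cranial-volume ratio is within 10%.

    Cranial volume is fixed anatomy, so a propagated mask whose volume
    drifts by more than 10% indicates a failed registration; such scans
    are excluded (with a logged reason) rather than analyzed.
    """
    if baseline_vol_ml <= 0 or followup_vol_ml <= 0:
        raise ValueError("volumes must be positive")
    return abs(followup_vol_ml / baseline_vol_ml - 1.0) <= QC_RATIO_TOLERANCE


def rigid_error(
    estimated: np.ndarray, truth: np.ndarray, center_mm: tuple[float, float, float]
) -> tuple[float, float]:
    """(translation error mm at ``center_mm``, rotation error degrees)."""
    d = np.linalg.inv(truth) @ estimated
    R = d[:3, :3]
    cos_angle = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    rot_deg = float(np.rad2deg(np.arccos(cos_angle)))
    c = np.append(np.asarray(center_mm, dtype=float), 1.0)
    trans_mm = float(np.linalg.norm((d @ c - c)[:3]))
    return trans_mm, rot_deg
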