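"""Synthetic head-CT phantoms with ground truth, and simulated cohorts.

This module is the test bed for the whole pipeline.  It produces:

* single head phantoms — ellipsoidal skull, brain, ventricular and sulcal
  CSF, optional infarct — together with exact voxelized truth masks;
* longitudinal series in which CSF contracts along a parametric edema
  trajectory while cranial volume stays constant (the Monro–Kellie
  constraint the CSF metric exploits), with optional known rigid motion
  between scans;
* simulated DICOM acquisitions (gantry tilt, variable slice thickness)
  for exercising ingestion;
* cohort-level CSF-volume tables with the continuous-time Markov
  correlation structure corr = a^|Δt| used by the longitudinal model.

Everything is a pure function of (spec, seed): identical inputs reproduce
identical outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .core import CTVolume, GeometryError, MaskVolume

__all__ = [
    "Ellipsoid",
    "SulcalShell",
    "PhantomSpec",
    "EdemaTrajectory",
    "RigidMotion",
    "TimePoint",
    "GeeSimSpec",
    "make_head_phantom",
    "make_phantom_cohort",
    "make_longitudinal_series",
    "simulate_gee_cohort",
    "simulate_age_csf_cohort",
    "simulate_mls_cohort",
    "write_dicom_series",
    "default_infarct",
]


# ---------------------------------------------------------------------------
# parametric geometry


@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center is an offset (mm) from the grid center."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise GeometryError(f"semi-axes must be positive, got {self.semi_axes}")

    def volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclasses.dataclass(frozen=True)
class SulcalShell:
    """Radial wedge pattern of peripheral (sulcal) CSF at the brain margin.

    CSF occupies the shell between ``inner_frac`` and ``outer_frac`` of the
    inner-skull ellipsoid, gated to ``n_folds`` angular wedges covering
    ``fill_frac`` of the circumference.
    """

    inner_frac: float = 0.90
    outer_frac: float = 0.98
    n_folds: int = 14
    fill_frac: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_frac < self.outer_frac < 1.0):
            raise GeometryError("need 0 < inner_frac < outer_frac < 1")
        if not (0.0 < self.fill_frac <= 1.0):
            raise GeometryError("fill_frac must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic head from which image and
    ground truth are generated together.

    HU defaults sit inside clinically plausible CT ranges; in particular
    infarct (18 HU) is deliberately close to CSF (8 HU) so that, under
    noise, the two compartments overlap in intensity — the confound the
    learned CSF classifier must resolve and a pure HU threshold cannot.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 26)
    spacing: tuple[float, float, float] = (2.75, 2.75, 5.0)
    skull_outer: tuple[float, float, float] = (82.0, 84.0, 62.0)
    skull_inner: tuple[float, float, float] = (74.0, 76.0, 55.0)
    ventricles: tuple[Ellipsoid, ...] = (
        Ellipsoid((-14.0, 0.0, 2.0), (9.0, 22.0, 11.0)),
        Ellipsoid((14.0, 0.0, 2.0), (9.0, 22.0, 11.0)),
    )
    sulci: SulcalShell | None = SulcalShell()
    infarct: Ellipsoid | None = None
    air_hu: float = -1000.0
    csf_hu: float = 8.0
    infarct_hu: float = 18.0
    brain_hu: float = 32.0
    skull_hu: float = 1000.0
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.air_hu < self.csf_hu < self.infarct_hu < self.brain_hu < self.skull_hu):
            raise GeometryError(
                "HU contrast ordering violated: need air < csf < infarct < brain < skull, got "
                f"{(self.air_hu, self.csf_hu, self.infarct_hu, self.brain_hu, self.skull_hu)}"
            )
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be non-negative")
        extent = tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))
        center = tuple(e / 2.0 for e in extent)
        for ax in range(3):
            if center[ax] - self.skull_outer[ax] < 0 or center[ax] + self.skull_outer[ax] > extent[ax]:
                raise GeometryError(
                    f"outer skull ellipsoid exceeds the grid on axis {ax}: "
                    f"semi-axis {self.skull_outer[ax]} mm vs extent {extent[ax]} mm"
                )
        if any(i >= o for i, o in zip(self.skull_inner, self.skull_outer)):
            raise GeometryError("inner skull semi-axes must be strictly smaller than outer")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))


def default_infarct() -> Ellipsoid:
    """A large right-hemisphere infarct (~90 ml, cortical+subcortical scale)."""
    return Ellipsoid((34.0, 8.0, 4.0), (28.0, 30.0, 26.0))


def _coord_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cx, cy, cz = spec.center_mm
    x = np.arange(spec.grid_shape[0]) * spec.spacing[0] - cx
    y = np.arange(spec.grid_shape[1]) * spec.spacing[1] - cy
    z = np.arange(spec.grid_shape[2]) * spec.spacing[2] - cz
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def _ellipsoid_mask(spec: PhantomSpec, ell: Ellipsoid) -> np.ndarray:
    X, Y, Z = _coord_grids(spec)
    a, b, c = ell.semi_axes
    ox, oy, oz = ell.center
    r2 = ((X - ox) / a) ** 2 + ((Y - oy) / b) ** 2 + ((Z - oz) / c) ** 2
    return r2 <= 1.0


def make_head_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict[str, MaskVolume]]:
    """Voxelize a head phantom and its exact truth masks.

    Returns the HU image (region mean + N(0, noise_sd²) noise) and masks
    for the cranial cavity (everything inside the inner skull surface),
    CSF and infarct.  CSF and infarct are disjoint subsets of the cranial
    mask; infarct never overwrites CSF.
    """
    spec.validate()
    outer = _ellipsoid_mask(spec, Ellipsoid((0.0, 0.0, 0.0), spec.skull_outer))
    inner = _ellipsoid_mask(spec, Ellipsoid((0.0, 0.0, 0.0), spec.skull_inner))
    skull = outer & ~inner
    cranial = inner

    csf = np.zeros(spec.grid_shape, dtype=bool)
    for vent in spec.ventricles:
        m = _ellipsoid_mask(spec, vent)
        if not m.any():
            raise GeometryError(f"ventricle {vent} voxelizes to nothing on this grid")
        if (m & ~cranial).any():
            raise GeometryError(f"ventricle {vent} extends outside the inner skull surface")
        csf |= m
    if spec.sulci is not None:
        csf |= _sulcal_mask(spec)

    infarct = np.zeros(spec.grid_shape, dtype=bool)
    if spec.infarct is not None:
        infarct = _ellipsoid_mask(spec, spec.infarct)
        if (infarct & ~cranial).any():
            raise GeometryError("infarct region extends outside the inner skull surface")
        infarct &= ~csf  # CSF truth takes precedence; compartments stay disjoint

    img = np.full(spec.grid_shape, spec.air_hu, dtype=np.float32)
    img[cranial] = spec.brain_hu
    img[skull] = spec.skull_hu
    img[infarct] = spec.infarct_hu
    img[csf] = spec.csf_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape).astype(np.float32)

    vol = CTVolume(img, spec.spacing)
    masks = {
        "cranial": MaskVolume(cranial, spec.spacing),
        "csf": MaskVolume(csf, spec.spacing),
        "infarct": MaskVolume(infarct, spec.spacing),
    }
    return vol, masks


def _sulcal_mask(spec: PhantomSpec) -> np.ndarray:
    sh = spec.sulci
    assert sh is not None
    X, Y, Z = _coord_grids(spec)
    a, b, c = spec.skull_inner
    r = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    shell = (r > sh.inner_frac) & (r <= sh.outer_frac)
    theta = np.arctan2(Y / b, X / a)
    gate = np.cos(sh.n_folds * theta) > np.cos(np.pi * sh.fill_frac)
    return shell & np.broadcast_to(gate, spec.grid_shape)


# ---------------------------------------------------------------------------
# longitudinal edema


@dataclasses.dataclass(frozen=True)
class EdemaTrajectory:
    """Monotone CSF contraction: exponential decay to an asymptotic floor.

    ``retained_fraction(t) = floor_frac + (1 − floor_frac)·exp(−rate·t)``
    with t in hours, so CSF volume never increases.  Midline shift stays
    zero while CSF loss is compensated, then grows linearly once the loss
    fraction exceeds ``threshold_frac``.
    """

    baseline_csf_frac: float = 0.08
    floor_frac: float = 0.5
    rate: float = 0.05
    mls_gain: float = 30.0
    threshold_frac: float = 0.35

    def __post_init__(self) -> None:
        if not (0.0 < self.floor_frac <= 1.0):
            raise ValueError("floor_frac must lie in (0, 1]")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not (0.0 <= self.threshold_frac < 1.0):
            raise ValueError("threshold_frac must lie in [0, 1)")

    def retained_fraction(self, t_hours: float) -> float:
        return self.floor_frac + (1.0 - self.floor_frac) * float(np.exp(-self.rate * t_hours))

    def mls_mm(self, loss_frac: float) -> float:
        return self.mls_gain * max(0.0, loss_frac - self.threshold_frac)


@dataclasses.dataclass(frozen=True)
class RigidMotion:
    """Known rigid motion (head repositioning) applied to a follow-up scan."""

    translation_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]
    center_mm: tuple[float, float, float]

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
        Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
        Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def as_matrix(self) -> np.ndarray:
        """4×4 map from original physical coordinates to moved coordinates."""
        R = self.rotation_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    @property
    def is_identity(self) -> bool:
        return not any(self.translation_mm) and not any(self.rotation_deg)


def apply_rigid(
    data: np.ndarray,
    spacing: Sequence[float],
    motion: RigidMotion,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``data`` under ``motion`` (moved(p) = original(motion⁻¹ p))."""
    if motion.is_identity:
        return data.copy()
    inv = np.linalg.inv(motion.as_matrix())
    s = np.asarray(spacing, dtype=float)
    # index-space affine: i_in = inv(R) i_out scaled by spacings + offset
    A = inv[:3, :3] * s[np.newaxis, :] / s[:, np.newaxis]
    off = inv[:3, 3] / s
    return ndimage.affine_transform(
        data.astype(np.float32) if order > 0 else data,
        A,
        offset=off,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,
    )


@dataclasses.dataclass
class TimePoint:
    """One scan of a longitudinal phantom series."""

    time_hours: float
    image: CTVolume
    truth: dict[str, MaskVolume]
    true_mls_mm: float
    motion: RigidMotion


def make_longitudinal_series(
    spec: PhantomSpec,
    traj: EdemaTrajectory,
    times_hours: Sequence[float],
    jitter: float = 0.0,
) -> list[TimePoint]:
    """Simulate serial scans of one head as edema evolves.

    CSF truth at time t is the baseline CSF eroded (via the Euclidean
    distance transform, outermost voxels first) to
    ``V0 · retained_fraction(t)``; vacated voxels are filled with brain so
    the cranial cavity volume is conserved.  Each follow-up is additionally
    moved by a random rigid transform of magnitude ≤ ``jitter`` (mm of
    translation and degrees of rotation per axis), recorded in the output
    so registration error is measurable.  Scan noise is drawn fresh per
    time point; geometry is independent of the noise.
    """
    times = [float(t) for t in times_hours]
    if len(times) == 0 or times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be sorted ascending and start at 0")
    base_spec = dataclasses.replace(spec, noise_sd=0.0)
    clean_img, truth0 = make_head_phantom(base_spec)
    csf0 = truth0["csf"].data
    n0 = int(csf0.sum())

    # erosion order: distance to the CSF boundary, ties broken by flat index
    dist = ndimage.distance_transform_edt(csf0, sampling=spec.spacing)
    flat_idx = np.flatnonzero(csf0)
    order_keys = np.lexsort((flat_idx, -dist[csf0]))
    ordered = flat_idx[order_keys]  # innermost (deep) CSF first

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2025]))
    out: list[TimePoint] = []
    for t in times:
        f = traj.retained_fraction(t)
        target = int(round(n0 * f))
        keep = np.zeros(csf0.size, dtype=bool)
        keep[ordered[:target]] = True
        csf_t = keep.reshape(csf0.shape)

        img = clean_img.data.copy()
        vacated = csf0 & ~csf_t
        img[vacated] = spec.brain_hu
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)

        if jitter > 0 and t > 0:
            motion = RigidMotion(
                translation_mm=tuple(rng.uniform(-jitter, jitter, size=3)),
                rotation_deg=tuple(rng.uniform(-jitter, jitter, size=3)),
                center_mm=spec.center_mm,
            )
        else:
            motion = RigidMotion((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), spec.center_mm)

        img_m = apply_rigid(img, spec.spacing, motion, order=1, cval=spec.air_hu)
        masks_m = {
            name: MaskVolume(
                apply_rigid(truth0[name].data if name != "csf" else csf_t, spec.spacing, motion, order=0),
                spec.spacing,
            )
            for name in ("cranial", "csf", "infarct")
        }
        loss = 1.0 - f
        out.append(
            TimePoint(
                time_hours=t,
                image=CTVolume(img_m, spec.spacing),
                truth=masks_m,
                true_mls_mm=traj.mls_mm(loss),
                motion=motion,
            )
        )
    return out


def make_phantom_cohort(
    n: int,
    seed: int = 0,
    infarct_frac: float = 0.5,
    noise_sd: float = 4.0,
) -> list[PhantomSpec]:
    """Specs for ``n`` anatomically varied heads (skull size, ventricle
    size, sulcal pattern vary a few percent; a fraction carry an infarct
    whose HU overlaps the CSF window under noise)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    specs = []
    for i in range(n):
        g = rng.uniform(0.92, 1.0)  # global head scale (1.0 fills the default grid)
        vent = rng.uniform(0.85, 1.2)
        spec = PhantomSpec(
            skull_outer=(82.0 * g, 84.0 * g, 62.0 * g),
            skull_inner=(74.0 * g, 76.0 * g, 55.0 * g),
            ventricles=(
                Ellipsoid((-14.0 * g, 0.0, 2.0), (9.0 * vent, 22.0 * vent, 11.0 * vent)),
                Ellipsoid((14.0 * g, 0.0, 2.0), (9.0 * vent, 22.0 * vent, 11.0 * vent)),
            ),
            sulci=SulcalShell(
                n_folds=int(rng.integers(12, 17)),
                fill_frac=float(rng.uniform(0.25, 0.35)),
            ),
            infarct=(
                Ellipsoid(
                    (float(rng.choice([-1, 1])) * 30.0 * g, float(rng.uniform(-6, 10)), 4.0),
                    (26.0 * g, 28.0 * g, 24.0 * g),
                )
                if rng.random() < infarct_frac
                else None
            ),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclasses.dataclass(frozen=True)
class GeeSimSpec:
    """Cohort simulator for the longitudinal CSF-volume model.

    Mean model  E(y_ij) = b0 + b1·t + b2·t² + b3·age + b4·ced  (t in days,
    age in years, ced the dichotomized edema-grade indicator); residuals
    follow the continuous-time Gaussian AR recursion whose stationary
    correlation is exactly corr(e_j, e_k) = a^|t_j − t_k|.

    Coefficient defaults follow the reported cohort-scale effects
    (intercept 1500 ml, −22 ml/day, +0.3 ml/day², +3.01 ml/year of age,
    −32.57 ml for edema grade 3); ages ~ N(67, 14²) and 32% grade-3
    prevalence mirror the study cohort.
    """

    n_subjects: int = 300
    coefficients: tuple[float, float, float, float, float] = (1500.0, -22.0, 0.3, 3.01, -32.57)
    a: float = 0.6
    sigma: float = 20.0
    age_mean: float = 67.0
    age_sd: float = 14.0
    ced_prob: float = 0.32
    scan_times: tuple[float, ...] | None = None
    n_scans_range: tuple[int, int] = (2, 5)
    followup_window_days: tuple[float, float] = (0.2, 5.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"correlation parameter a must lie in (0, 1), got {self.a}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.scan_times is not None:
            st = self.scan_times
            if len(st) < 1 or any(b <= a_ for a_, b in zip(st, st[1:])):
                raise ValueError("scan_times must be non-empty and strictly increasing")


def simulate_gee_cohort(sim: GeeSimSpec) -> pd.DataFrame:
    """Simulate per-scan CSF volumes with Markov within-subject correlation.

    Returns a tidy table with one row per scan: subject_id, age_years,
    ced3, time_days, csf_ml.
    """
    sim.validate()
    rng = np.random.default_rng(sim.seed)
    b0, b1, b2, b3, b4 = sim.coefficients
    rows = []
    for i in range(sim.n_subjects):
        age = rng.normal(sim.age_mean, sim.age_sd)
        ced = int(rng.random() < sim.ced_prob)
        if sim.scan_times is not None:
            times = np.asarray(sim.scan_times, dtype=float)
        else:
            n = int(rng.integers(sim.n_scans_range[0], sim.n_scans_range[1] + 1))
            fu = np.sort(rng.uniform(*sim.followup_window_days, size=n - 1))
            times = np.concatenate([[0.0], fu])
            while np.any(np.diff(times) <= 0):  # guard against duplicate draws
                fu = np.sort(rng.uniform(*sim.followup_window_days, size=n - 1))
                times = np.concatenate([[0.0], fu])
        mean = b0 + b1 * times + b2 * times**2 + b3 * age + b4 * ced
        resid = _markov_residuals(times, sim.a, sim.sigma, rng)
        for t, mu, e in zip(times, mean, resid):
            rows.append(
                {
                    "subject_id": f"sub-{i:04d}",
                    "age_years": float(age),
                    "ced3": ced,
                    "time_days": float(t),
                    "csf_ml": float(mu + e),
                }
            )
    return pd.DataFrame(rows)


def _markov_residuals(times: np.ndarray, a: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian AR recursion: e_k = a^Δt e_{k−1} + σ√(1−a^{2Δt}) z."""
    e = np.empty(len(times))
    e[0] = sigma * rng.standard_normal()
    for k in range(1, len(times)):
        rho = a ** (times[k] - times[k - 1])
        e[k] = rho * e[k - 1] + sigma * np.sqrt(1.0 - rho**2) * rng.standard_normal()
    return e


def simulate_age_csf_cohort(
    n: int = 150,
    slope_pct_per_year: float = 0.25,
    target_r: float = 0.74,
    age_mean: float = 67.0,
    age_sd: float = 14.0,
    intercept_pct_at_40: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Baseline CSF (% of cranial volume) vs age, as brain atrophy proxy.

    Noise SD is set so the *population* Pearson correlation equals
    ``target_r`` given the age spread: sd = slope·age_sd·sqrt(1/r² − 1).
    """
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    age = rng.normal(age_mean, age_sd, size=n)
    noise_sd = slope_pct_per_year * age_sd * np.sqrt(1.0 / target_r**2 - 1.0)
    csf_pct = intercept_pct_at_40 + slope_pct_per_year * (age - 40.0) + rng.normal(0.0, noise_sd, size=n)
    csf_pct = np.clip(csf_pct, 0.5, None)
    return pd.DataFrame({"age_years": age, "baseline_csf_pct": csf_pct})


def simulate_mls_cohort(
    n: int = 100,
    traj: EdemaTrajectory | None = None,
    loss_range_pct: tuple[float, float] = (5.0, 60.0),
    noise_sd_mm: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject (maximal CSF reduction %, peak midline shift mm) pairs.

    MLS follows the trajectory's compensation rule — zero until the loss
    fraction exceeds the threshold, then linear in the excess — plus
    measurement noise, clipped at 0 (MLS is read as a non-negative mm).
    """
    traj = traj or EdemaTrajectory()
    rng = np.random.default_rng(seed)
    loss_pct = rng.uniform(*loss_range_pct, size=n)
    mls = np.array([traj.mls_mm(lp / 100.0) for lp in loss_pct])
    mls = np.clip(mls + rng.normal(0.0, noise_sd_mm, size=n), 0.0, None)
    return pd.DataFrame({"max_reduction_pct": loss_pct, "peak_mls_mm": mls})


# ---------------------------------------------------------------------------
# simulated DICOM acquisition


def write_dicom_series(
    vol: CTVolume,
    out_dir: str | Path,
    tilt_deg: float = 0.0,
    thickness_profile: float | Sequence[float] = 5.0,
    series_description: str = "HEAD AXIAL STANDARD",
    kernel: str = "STANDARD",
    derived: bool = False,
    patient_id: str = "PHANTOM",
    series_number: int = 1,
    acquisition_datetime: str = "20200101T120000",
    thickness_tag_override: float | None = None,
) -> list[Path]:
    """Emit a single-frame CT DICOM series simulating a (possibly tilted,
    possibly variable-thickness) axial acquisition of ``vol``.

    The gantry tilt is encoded the way scanners do: orientation cosines
    stay axial while consecutive ImagePositionPatient tags advance along
    the tilted slice normal, so the Euclidean gap between positions equals
    the nominal inter-slice distance while the in-plane origin drifts by
    gap·sinθ per slice (equivalently z_gap·tanθ).  Pixel data are sampled
    from the volume on those tilted positions, so a naive stack is sheared
    and ingestion must undo the shear.

    ``thickness_profile`` is either a scalar (uniform gaps covering the
    volume) or an explicit per-gap list; the series then holds
    ``len(profile) + 1`` slices.  ``thickness_tag_override`` deliberately
    writes a wrong SliceThickness tag, for testing that geometry is always
    derived from positions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    theta = np.deg2rad(tilt_deg)
    nx, ny, nz = vol.shape
    sx, sy, sz = vol.spacing
    extent_z = (nz - 1) * sz

    if np.isscalar(thickness_profile):
        d = float(thickness_profile)  # type: ignore[arg-type]
        if d <= 0:
            raise ValueError("slice thickness must be positive")
        n_gaps = int(np.floor(extent_z / (d * np.cos(theta))))
        gaps = [d] * n_gaps
    else:
        gaps = [float(g) for g in thickness_profile]  # type: ignore[union-attr]
        if any(g <= 0 for g in gaps):
            raise ValueError("slice thickness must be positive")

    # physical slice trajectory: advance along the tilted normal, with the
    # in-plane drift pivoting about the mid-stack slice (gantry isocenter)
    z_pos = np.concatenate([[0.0], np.cumsum([g * np.cos(theta) for g in gaps])])
    y_drift = np.concatenate([[0.0], np.cumsum([g * np.sin(theta) for g in gaps])])
    y_drift = y_drift - y_drift[int(np.argmin(np.abs(z_pos - z_pos[-1] / 2.0)))]
    if z_pos[-1] > extent_z + 1e-6:
        raise GeometryError("requested slice stack extends beyond the volume")

    series_uid = generate_uid(entropy_srcs=[patient_id, series_description, str(series_number)])
    study_uid = generate_uid(entropy_srcs=[patient_id, "study"])
    frame_uid = generate_uid(entropy_srcs=[patient_id, "frame"])
    files: list[Path] = []
    yi = np.arange(ny, dtype=float)
    for k, (zk, yk) in enumerate(zip(z_pos, y_drift)):
        sl = _sample_tilted_slice(vol.data, zk / sz, yk / sy, yi)
        pixels = np.clip(np.round(sl + 1100.0), 0, 65535).astype(np.uint16)
        ds = _ct_dataset(
            pixels.T,  # DICOM rows = y, cols = x
            series_uid=series_uid,
            study_uid=study_uid,
            frame_uid=frame_uid,
            sop_uid=generate_uid(entropy_srcs=[series_uid, str(k)]),
            instance_number=k + 1,
            position=(vol.origin[0], vol.origin[1] + yk, vol.origin[2] + zk),
            pixel_spacing=(sy, sx),
            thickness=thickness_tag_override
            if thickness_tag_override is not None
            else (gaps[min(k, len(gaps) - 1)]),
            tilt_deg=tilt_deg,
            series_description=series_description,
            kernel=kernel,
            derived=derived,
            patient_id=patient_id,
            series_number=series_number,
            acquisition_datetime=acquisition_datetime,
        )
        path = out_dir / f"slice_{k:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        files.append(path)
    return files


def _sample_tilted_slice(data: np.ndarray, z_idx: float, y_shift_idx: float, yi: np.ndarray) -> np.ndarray:
    """Linear sample of the volume at fractional z, shifted along y."""
    nz = data.shape[2]
    z0 = int(np.floor(z_idx))
    z1 = min(z0 + 1, nz - 1)
    w = z_idx - z0
    plane = (1.0 - w) * data[:, :, z0] + w * data[:, :, z1]
    if abs(y_shift_idx) < 1e-12:
        return plane
    # value at output row r comes from input y = r + shift (head fixed, slice origin drifted)
    coords = yi + y_shift_idx
    out = np.empty_like(plane)
    for ix in range(plane.shape[0]):
        out[ix] = np.interp(coords, yi, plane[ix], left=plane[ix, 0], right=plane[ix, -1])
    return out


def _ct_dataset(
    pixels: np.ndarray,
    *,
    series_uid: str,
    study_uid: str,
    frame_uid: str,
    sop_uid: str,
    instance_number: int,
    position: tuple[float, float, float],
    pixel_spacing: tuple[float, float],
    thickness: float,
    tilt_deg: float,
    series_description: str,
    kernel: str,
    derived: bool,
    patient_id: str,
    series_number: int,
    acquisition_datetime: str,
) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "CT"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.FrameOfReferenceUID = frame_uid
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.SeriesDescription = series_description
    ds.ConvolutionKernel = kernel
    ds.ImageType = ["DERIVED" if derived else "ORIGINAL", "PRIMARY", "AXIAL"]
    date, time = acquisition_datetime.split("T")
    ds.AcquisitionDate = date
    ds.AcquisitionTime = time
    ds.StudyDate = date
    ds.StudyTime = "000000"
    ds.ImagePositionPatient = [f"{v:.6f}" for v in position]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.PixelSpacing = [f"{pixel_spacing[0]:.6f}", f"{pixel_spacing[1]:.6f}"]
    ds.SliceThickness = f"{thickness:.6f}"
    ds.GantryDetectorTilt = f"{tilt_deg:.4f}"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1100"
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(pixels).tobytes()
    return ds
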