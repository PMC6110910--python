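"""Phantom generator: geometry, trajectories, cohort simulators, DICOM."""

import dataclasses

import numpy as np
import pytest

from edemascan.core import GeometryError
from edemascan.phantom import (
    EdemaTrajectory,
    Ellipsoid,
    GeeSimSpec,
    PhantomSpec,
    make_head_phantom,
    make_longitudinal_series,
    simulate_gee_cohort,
    write_dicom_series,
)


def sphere_spec(radius_mm=20.0, spacing=1.0, n=48, noise=0.0):
    return PhantomSpec(
        grid_shape=(n, n, n),
        spacing=(spacing,) * 3,
        skull_outer=(radius_mm + 2.5,) * 3,
        skull_inner=(radius_mm + 2.0,) * 3,
        ventricles=(Ellipsoid((0.0, 0.0, 0.0), (radius_mm,) * 3),),
        sulci=None,
        noise_sd=noise,
    )


class TestMakeHeadPhantom:
    def test_spherical_ventricle_matches_analytic_volume(self):
        vol, masks = make_head_phantom(sphere_spec())
        expected = 4.0 / 3.0 * np.pi * 20.0**3 / 1000.0  # 33.51 ml
        assert masks["csf"].volume_ml() == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("semi_axes", [(15.0, 10.0, 8.0), (18.0, 18.0, 12.0)])
    def test_ellipsoid_volumes_within_voxelization_error(self, semi_axes):
        spec = dataclasses.replace(
            sphere_spec(), ventricles=(Ellipsoid((0.0, 0.0, 0.0), semi_axes),)
        )
        _, masks = make_head_phantom(spec)
        a, b, c = semi_axes
        expected = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        assert masks["csf"].volume_ml() == pytest.approx(expected, rel=0.015)

    def test_noise_independent_of_geometry(self):
        s1 = dataclasses.replace(PhantomSpec(), noise_sd=5.0, seed=1)
        s2 = dataclasses.replace(PhantomSpec(), noise_sd=5.0, seed=2)
        v1, m1 = make_head_phantom(s1)
        v2, m2 = make_head_phantom(s2)
        assert np.array_equal(m1["csf"].data, m2["csf"].data)
        assert not np.array_equal(v1.data, v2.data)

    def test_determinism(self):
        spec = PhantomSpec(seed=9, noise_sd=4.0)
        v1, m1 = make_head_phantom(spec)
        v2, m2 = make_head_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(m1["cranial"].data, m2["cranial"].data)

    def test_infarct_region_mean_hu(self):
        from edemascan.phantom import default_infarct

        spec = PhantomSpec(seed=4, noise_sd=2.0, infarct=default_infarct(), infarct_hu=18.0, csf_hu=8.0)
        vol, masks = make_head_phantom(spec)
        assert masks["infarct"].count() > 1000
        assert vol.data[masks["infarct"].data].mean() == pytest.approx(18.0, abs=1.0)

    def test_compartments_nested_and_disjoint(self, default_phantom):
        _, _, masks = default_phantom
        assert not (masks["csf"].data & ~masks["cranial"].data).any()
        assert not (masks["infarct"].data & ~masks["cranial"].data).any()
        assert not (masks["csf"].data & masks["infarct"].data).any()

    def test_geometry_exceeding_grid_rejected(self):
        spec = dataclasses.replace(PhantomSpec(), skull_outer=(120.0, 84.0, 62.0))
        with pytest.raises(GeometryError):
            make_head_phantom(spec)

    def test_hu_ordering_enforced(self):
        spec = dataclasses.replace(PhantomSpec(), csf_hu=40.0)
        with pytest.raises(GeometryError):
            make_head_phantom(spec)


class TestLongitudinalSeries:
    def test_no_edema_keeps_csf_constant(self):
        traj = EdemaTrajectory(floor_frac=1.0)
        series = make_longitudinal_series(PhantomSpec(seed=5), traj, [0.0, 24.0, 96.0])
        vols = [tp.truth["csf"].volume_ml() for tp in series]
        assert max(vols) / min(vols) == pytest.approx(1.0, rel=0.01)
        assert all(tp.true_mls_mm == 0.0 for tp in series)

    def test_halving_trajectory_reaches_floor(self):
        traj = EdemaTrajectory(floor_frac=0.5, rate=1.0, threshold_frac=0.35)
        series = make_longitudinal_series(PhantomSpec(seed=5), traj, [0.0, 96.0])
        v0, v1 = (tp.truth["csf"].volume_ml() for tp in series)
        assert v1 / v0 == pytest.approx(0.5, abs=0.01)
        assert series[1].true_mls_mm > 0  # loss 0.5 > threshold 0.35

    def test_trajectory_matches_closed_form_at_all_times(self):
        traj = EdemaTrajectory(floor_frac=0.6, rate=0.05)
        times = [0.0, 12.0, 48.0, 110.0]
        series = make_longitudinal_series(PhantomSpec(seed=5), traj, times)
        v0 = series[0].truth["csf"].volume_ml()
        for tp in series:
            assert tp.truth["csf"].volume_ml() / v0 == pytest.approx(
                traj.retained_fraction(tp.time_hours), abs=0.01
            )

    def test_cranial_volume_conserved(self):
        series = make_longitudinal_series(PhantomSpec(seed=5), EdemaTrajectory(), [0.0, 48.0, 96.0])
        vols = [tp.truth["cranial"].volume_ml() for tp in series]
        assert max(vols) / min(vols) == pytest.approx(1.0, rel=0.02)

    def test_zero_jitter_changes_only_compartments(self):
        spec = PhantomSpec(seed=5, noise_sd=0.0)
        series = make_longitudinal_series(spec, EdemaTrajectory(floor_frac=0.7, rate=1.0), [0.0, 96.0], jitter=0.0)
        b, f = series
        diff = b.image.data != f.image.data
        changed = b.truth["csf"].data & ~f.truth["csf"].data
        assert np.array_equal(diff, changed)  # vacated voxels only

    def test_monotone_non_increasing_csf(self):
        traj = EdemaTrajectory(floor_frac=0.5, rate=0.03)
        series = make_longitudinal_series(PhantomSpec(seed=6), traj, [0.0, 10.0, 30.0, 80.0])
        vols = [tp.truth["csf"].count() for tp in series]
        assert all(b <= a for a, b in zip(vols, vols[1:]))

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            make_longitudinal_series(PhantomSpec(), EdemaTrajectory(), [0.0, 48.0, 24.0])

    def test_jitter_recorded(self):
        series = make_longitudinal_series(PhantomSpec(seed=7), EdemaTrajectory(), [0.0, 24.0], jitter=3.0)
        assert series[0].motion.is_identity
        assert not series[1].motion.is_identity
        assert np.all(np.abs(series[1].motion.translation_mm) <= 3.0)


class TestGeeSimulator:
    def test_noiseless_equals_linear_predictor(self):
        sim = GeeSimSpec(n_subjects=20, sigma=0.0, scan_times=(0.0, 1.0, 3.0), seed=1)
        df = simulate_gee_cohort(sim)
        b0, b1, b2, b3, b4 = sim.coefficients
        mu = b0 + b1 * df.time_days + b2 * df.time_days**2 + b3 * df.age_years + b4 * df.ced3
        assert np.allclose(df.csf_ml, mu)

    def test_adjacent_pair_correlation_matches_a(self):
        sim = GeeSimSpec(n_subjects=10_000, a=0.5, scan_times=(0.0, 1.0), seed=3)
        df = simulate_gee_cohort(sim)
        b0, b1, b2, b3, b4 = sim.coefficients
        resid = df.csf_ml - (b0 + b1 * df.time_days + b2 * df.time_days**2 + b3 * df.age_years + b4 * df.ced3)
        r0 = resid[df.time_days == 0.0].to_numpy()
        r1 = resid[df.time_days == 1.0].to_numpy()
        corr = np.corrcoef(r0, r1)[0, 1]
        mc_se = 1.0 / np.sqrt(len(r0))
        assert abs(corr - 0.5) < 3 * mc_se

    def test_near_zero_a_gives_uncorrelated_residuals(self):
        sim = GeeSimSpec(n_subjects=10_000, a=1e-8, scan_times=(0.0, 1.0), seed=4)
        df = simulate_gee_cohort(sim)
        b0, b1, b2, b3, b4 = sim.coefficients
        resid = df.csf_ml - (b0 + b1 * df.time_days + b2 * df.time_days**2 + b3 * df.age_years + b4 * df.ced3)
        corr = np.corrcoef(resid[df.time_days == 0.0], resid[df.time_days == 1.0])[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(10_000)

    @pytest.mark.parametrize("bad_a", [0.0, 1.0, 1.3, -0.2])
    def test_invalid_a_rejected(self, bad_a):
        with pytest.raises(ValueError):
            simulate_gee_cohort(GeeSimSpec(n_subjects=5, a=bad_a))

    def test_correlation_fidelity_across_gaps(self):
        for dt in (0.5, 2.0, 4.0):
            sim = GeeSimSpec(n_subjects=10_000, a=0.6, scan_times=(0.0, dt), seed=int(dt * 10))
            df = simulate_gee_cohort(sim)
            b0, b1, b2, b3, b4 = sim.coefficients
            resid = df.csf_ml - (
                b0 + b1 * df.time_days + b2 * df.time_days**2 + b3 * df.age_years + b4 * df.ced3
            )
            corr = np.corrcoef(resid[df.time_days == 0.0], resid[df.time_days == dt])[0, 1]
            expected = 0.6**dt
            mc_se = (1 - expected**2) / np.sqrt(10_000)
            assert abs(corr - expected) < 3 * mc_se


class TestDicomWriter:
    def test_untilted_uniform_positions(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, tilt_deg=0.0, thickness_profile=5.0)
        import pydicom

        files = sorted(tmp_path.glob("*.dcm"))
        pos = np.array([pydicom.dcmread(f).ImagePositionPatient for f in files], dtype=float)
        pos = pos[np.argsort(pos[:, 2])]
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(gaps, 5.0, atol=1e-6)

    def test_tilt_encodes_drift_over_z_advance(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, tilt_deg=20.0, thickness_profile=5.0)
        import pydicom

        files = sorted(tmp_path.glob("*.dcm"))
        pos = np.array([pydicom.dcmread(f).ImagePositionPatient for f in files], dtype=float)
        pos = pos[np.argsort(pos[:, 2])]
        steps = np.diff(pos, axis=0)
        # consecutive positions still 5 mm apart; in-plane drift per z-gap = tan(20°)
        assert np.allclose(np.linalg.norm(steps, axis=1), 5.0, atol=1e-4)
        assert np.allclose(steps[:, 1] / steps[:, 2], np.tan(np.deg2rad(20.0)), atol=1e-4)

    def test_explicit_thickness_profile_emitted_exactly(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        profile = [5.0, 5.0, 5.0, 2.0, 2.0, 2.0]
        write_dicom_series(vol, tmp_path, tilt_deg=0.0, thickness_profile=profile)
        import pydicom

        files = sorted(tmp_path.glob("*.dcm"))
        assert len(files) == len(profile) + 1
        pos = np.array([pydicom.dcmread(f).ImagePositionPatient for f in files], dtype=float)
        pos = pos[np.argsort(pos[:, 2])]
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(gaps, profile, atol=1e-6)

    def test_nonpositive_thickness_rejected(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        with pytest.raises(ValueError):
            write_dicom_series(vol, tmp_path, thickness_profile=[5.0, -1.0])
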