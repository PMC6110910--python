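"""DICOM ingestion: spacing from positions, tilt correction, resampling,
series selection, NIfTI conversion."""

import numpy as np
import pytest
from scipy import ndimage

from edemascan.core import EdemascanError, dice, load_ct_nifti, resample_like
from edemascan.ingest import (
    DicomSeries,
    DicomSlice,
    compute_slice_spacing,
    convert_to_nifti,
    correct_gantry_tilt,
    ingest_and_convert,
    ingest_series,
    load_dicom_dir,
    resample_uniform_thickness,
    select_axial_brain_series,
)
from edemascan.phantom import Ellipsoid, PhantomSpec, make_head_phantom, write_dicom_series

AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def synthetic_series(z_positions, pixels=None, thickness=5.0, **kwargs):
    shape = (12, 10)
    slices = [
        DicomSlice(
            pixels=(pixels[k] if pixels is not None else np.zeros(shape, dtype=np.float32)),
            position=(0.0, 0.0, float(z)),
            orientation=AXIAL,
            thickness=thickness,
            pixel_spacing=(1.0, 1.0),
        )
        for k, z in enumerate(z_positions)
    ]
    return DicomSeries(slices=slices, **kwargs)


class TestSliceSpacing:
    def test_uniform_stack(self):
        gaps, uniform = compute_slice_spacing(synthetic_series([0, 5, 10, 15]))
        assert gaps == pytest.approx([5.0, 5.0, 5.0])
        assert uniform

    def test_variable_stack(self):
        gaps, uniform = compute_slice_spacing(synthetic_series([0, 5, 10, 12, 14]))
        assert gaps == pytest.approx([5.0, 5.0, 2.0, 2.0])
        assert not uniform

    def test_duplicate_positions_named(self):
        with pytest.raises(EdemascanError, match="slices 1 and 2"):
            compute_slice_spacing(synthetic_series([0, 5, 5, 10]))

    def test_tilted_series_keeps_nominal_gap(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, tilt_deg=20.0, thickness_profile=5.0)
        gaps, uniform = compute_slice_spacing(load_dicom_dir(tmp_path)[0])
        assert np.allclose(gaps, 5.0, atol=1e-3)
        assert uniform

    def test_spacing_ignores_thickness_tags(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, tilt_deg=0.0, thickness_profile=5.0, thickness_tag_override=1.7)
        series = load_dicom_dir(tmp_path)[0]
        assert series.slices[0].thickness == pytest.approx(1.7)
        gaps, _ = compute_slice_spacing(series)
        assert np.allclose(gaps, 5.0, atol=1e-6)
        rec = ingest_series(series)
        assert rec.spacing[2] == pytest.approx(5.0, abs=1e-6)


def reconstructed_cranial(rec):
    """Threshold oracle: interior enclosed by the skull ring (slice-wise
    fill so a stack that stops inside the vault still closes)."""
    skull = rec.data > 500
    out = np.zeros_like(skull)
    for k in range(skull.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(skull[:, :, k])
    return out & ~skull


class TestGantryTilt:
    def test_untilted_is_passthrough(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, tilt_deg=0.0, thickness_profile=5.0)
        rec = correct_gantry_tilt(load_dicom_dir(tmp_path)[0])
        # phantom HU are integers, so pass-through is exact
        assert np.array_equal(rec.data, vol.data[:, :, : rec.shape[2]])

    def test_tilted_roundtrip_recovers_geometry(self, tmp_path):
        spec = PhantomSpec(seed=1, noise_sd=0.0)
        vol, masks = make_head_phantom(spec)
        write_dicom_series(vol, tmp_path, tilt_deg=20.0, thickness_profile=5.0)
        rec = correct_gantry_tilt(load_dicom_dir(tmp_path)[0])
        cran = reconstructed_cranial(rec)
        truth = resample_like(masks["cranial"], rec, order=0)
        assert dice(cran, truth.data) >= 0.98
        v = cran.sum() * np.prod(rec.spacing) / 1000.0
        assert v == pytest.approx(masks["cranial"].volume_ml(), rel=0.02)
        # interior HU mass (eroded to avoid the partial-volume rim) within 1%
        core = ndimage.binary_erosion(truth.data, iterations=2)
        core_orig = ndimage.binary_erosion(masks["cranial"].data, iterations=2)
        assert rec.data[core].mean() == pytest.approx(vol.data[core_orig].mean(), rel=0.01)

    def test_straight_rod_collinear_after_correction(self, tmp_path):
        spec = PhantomSpec(seed=1, noise_sd=0.0, sulci=None, ventricles=(Ellipsoid((0, 0, 0), (4, 4, 50)),))
        vol, _ = make_head_phantom(spec)
        write_dicom_series(vol, tmp_path, tilt_deg=20.0, thickness_profile=5.0)
        series = load_dicom_dir(tmp_path)[0]
        naive = np.stack([sl.pixels for sl in series.slices], axis=-1)
        rec = correct_gantry_tilt(series)

        def rod_centroids(arr):
            out = []
            for k in range(arr.shape[2]):
                w = np.abs(arr[:, :, k] - 8.0) < 2.0
                if w.sum() > 2:
                    out.append(np.argwhere(w)[:, 1].mean())
            return np.array(out)

        sheared = rod_centroids(naive)
        corrected = rod_centroids(rec.data)
        assert sheared.max() - sheared.min() > 5.0  # visibly sheared naive stack
        assert np.abs(corrected - corrected.mean()).max() < 1.0  # collinear


class TestUniformResampling:
    def test_min_gap_rule(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, thickness_profile=[5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 2, 2, 2, 2, 2])
        rec = resample_uniform_thickness(load_dicom_dir(tmp_path)[0])
        assert rec.spacing[2] == pytest.approx(2.0, abs=1e-6)

    def test_uniform_series_is_bit_identical_passthrough(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        write_dicom_series(vol, tmp_path, thickness_profile=5.0)
        rec = resample_uniform_thickness(load_dicom_dir(tmp_path)[0])
        assert np.array_equal(rec.data, vol.data[:, :, : rec.shape[2]])

    def test_csf_volume_preserved_through_resampling(self, tmp_path):
        # columnar ventricles (the z-coherent CSF compartment); volume read
        # with a linear partial-volume estimate so midpoint mixtures count
        # fractionally instead of falling on a threshold knife edge
        spec = PhantomSpec(
            seed=1, noise_sd=0.0, sulci=None,
            ventricles=(Ellipsoid((-18, 0, 0), (10, 18, 44)), Ellipsoid((18, 0, 0), (10, 18, 44))),
        )
        vol, masks = make_head_phantom(spec)
        profile = [5.0] * 13 + [2.5] * 24
        write_dicom_series(vol, tmp_path, thickness_profile=profile)
        rec = resample_uniform_thickness(load_dicom_dir(tmp_path)[0])
        cran = resample_like(masks["cranial"], rec, order=0)
        frac = np.clip((spec.brain_hu - rec.data) / (spec.brain_hu - spec.csf_hu), 0.0, 1.0)
        frac[~cran.data] = 0.0
        v = float(frac.sum() * np.prod(rec.spacing) / 1000.0)
        assert v == pytest.approx(masks["csf"].volume_ml(), rel=0.02)


def make_session_series(tmp_path, vol, variants):
    dirs = []
    for i, kwargs in enumerate(variants):
        d = tmp_path / f"series_{i}"
        write_dicom_series(vol, d, thickness_profile=8.0, patient_id=f"S{i}", series_number=i + 1, **kwargs)
        dirs.append(d)
    series = []
    for d in dirs:
        series.extend(load_dicom_dir(d))
    return series


@pytest.fixture(scope="module")
def vol():
    return make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))[0]


class TestSeriesSelection:

    def test_bone_kernel_excluded(self, tmp_path, vol):
        session = make_session_series(
            tmp_path, vol, [{"kernel": "STANDARD"}, {"kernel": "BONEPLUS"}]
        )
        assert select_axial_brain_series(session).kernel == "STANDARD"

    def test_single_valid_series_returned(self, tmp_path, vol):
        session = make_session_series(tmp_path, vol, [{}])
        assert select_axial_brain_series(session) is session[0]

    def test_derived_only_session_errors_with_reasons(self, tmp_path, vol):
        session = make_session_series(tmp_path, vol, [{"derived": True}])
        with pytest.raises(EdemascanError, match="derived"):
            select_axial_brain_series(session)

    def test_lexicon_exclusion(self, tmp_path, vol):
        session = make_session_series(
            tmp_path, vol,
            [{"series_description": "CTA ANGIO HEAD"}, {"series_description": "HEAD AXIAL"}],
        )
        assert select_axial_brain_series(session).description == "HEAD AXIAL"


class TestNiftiConversion:
    def test_roundtrip_and_header(self, tmp_path):
        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=2.0))
        vol.acquisition_time = "20200101T120000"
        nii, sidecar = convert_to_nifti(vol, "42", tmp_path)
        assert nii.name == "sub-42_ses-20200101T120000_ct.nii.gz"
        back = load_ct_nifti(nii)
        assert np.allclose(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_sidecar_records_tilt(self, tmp_path):
        import json

        vol, _ = make_head_phantom(PhantomSpec(seed=1, noise_sd=0.0))
        dcm_dir = tmp_path / "dcm"
        write_dicom_series(vol, dcm_dir, tilt_deg=15.0, thickness_profile=5.0)
        nii, sidecar = ingest_and_convert(dcm_dir, "07", tmp_path / "bids")
        meta = json.loads(sidecar.read_text())
        assert meta["GantryTilt"] == pytest.approx(15.0, abs=0.01)
        assert meta["GantryTiltTag"] == pytest.approx(15.0)


class TestGeometryFidelityProperty:
    @pytest.mark.parametrize("tilt,profile", [(10.0, 4.0), (25.0, [5.0] * 20 + [2.0] * 18)])
    def test_ingest_preserves_cranial_compartment(self, tmp_path, tilt, profile):
        spec = PhantomSpec(seed=8, noise_sd=0.0)
        vol, masks = make_head_phantom(spec)
        write_dicom_series(vol, tmp_path, tilt_deg=tilt, thickness_profile=profile)
        rec = ingest_series(load_dicom_dir(tmp_path)[0])
        cran = reconstructed_cranial(rec)
        truth = resample_like(masks["cranial"], rec, order=0)
        assert dice(cran, truth.data) >= 0.98
        v = cran.sum() * np.prod(rec.spacing) / 1000.0
        assert v == pytest.approx(masks["cranial"].volume_ml(), rel=0.02)
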