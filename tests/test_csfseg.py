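"""CSF segmentation: integral volume, Haar features, forest, contour,
infarct cleaning."""

import numpy as np
import pytest
from scipy import ndimage

from edemascan.core import CTVolume, DegenerateInputError, GridMismatchError, MaskVolume, dice
from edemascan.csfseg import (
    HaarFeatureSpec,
    box_sum,
    clean_with_infarct_mask,
    haar_features,
    integral_volume,
    load_classifier,
    predict_csf,
    refine_active_contour,
    save_classifier,
    threshold_baseline_segment,
    train_csf_classifier,
)
from edemascan.phantom import PhantomSpec, make_head_phantom, make_phantom_cohort


class TestIntegralVolume:
    def test_constant_volume_box(self):
        iv = integral_volume(np.ones((10, 10, 10)))
        lo = np.array([[2, 3, 1]])
        hi = np.array([[5, 6, 4]])
        assert box_sum(iv, lo, hi)[0] == 64.0

    def test_random_boxes_match_bruteforce(self, rng):
        data = rng.integers(-1000, 1000, size=(18, 15, 12)).astype(np.float64)
        iv = integral_volume(data)
        for _ in range(50):
            lo = np.array([rng.integers(0, s) for s in data.shape])
            hi = np.array([rng.integers(l, s) for l, s in zip(lo, data.shape)])
            expected = data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1].sum()
            assert box_sum(iv, lo[None], hi[None])[0] == expected

    def test_single_voxel_box_returns_raw_value(self, rng):
        data = rng.normal(size=(6, 6, 6))
        iv = integral_volume(data)
        c = np.array([[3, 2, 4]])
        assert box_sum(iv, c, c)[0] == pytest.approx(data[3, 2, 4])


class TestHaarFeatures:
    def test_uniform_volume_gives_zero_differences(self):
        vol = CTVolume(np.full((30, 30, 10), 25.0), (1, 1, 1))
        spec = HaarFeatureSpec(include_raw=False)
        f = haar_features(vol, np.array([[15, 15, 5]]), spec)
        diff_cols = [i for i, _ in enumerate(np.tile(spec.patterns, len(spec.scales)))
                     if spec.patterns[i % len(spec.patterns)] != "center"]
        assert np.allclose(f[0, diff_cols], 0.0, atol=1e-9)

    def test_step_edge_left_right_difference(self):
        data = np.full((40, 40, 8), 10.0)
        data[20:, :, :] = 40.0  # step of 30 HU along x, edge between 19 and 20
        vol = CTVolume(data, (1, 1, 1))
        spec = HaarFeatureSpec(scales=(2,), patterns=("left_right", "up_down"), include_raw=False)
        f = haar_features(vol, np.array([[19, 20, 4]]), spec)
        assert f[0, 0] == pytest.approx(-30.0)  # left box low, right box high
        assert f[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_constant_region_raw_channels(self):
        vol = CTVolume(np.full((30, 30, 10), 17.0), (1, 1, 1))
        spec = HaarFeatureSpec(scales=(1,), patterns=("center",), include_raw=True)
        f = haar_features(vol, np.array([[15, 15, 5]]), spec)
        assert f[0].tolist() == pytest.approx([17.0, 17.0, 17.0, 0.0])  # center, raw, mean, sd


class TestForest:
    def test_separable_problem_high_oob(self):
        spec = PhantomSpec(seed=31, noise_sd=0.0)
        vol, masks = make_head_phantom(spec)
        clf = train_csf_classifier([(vol, masks["cranial"], masks["csf"])], seed=1, per_class_cap=2000)
        assert clf.oob_accuracy >= 0.99

    def test_training_deterministic(self):
        spec = PhantomSpec(seed=32)
        vol, masks = make_head_phantom(spec)
        args = ([(vol, masks["cranial"], masks["csf"])],)
        c1 = train_csf_classifier(*args, seed=4, per_class_cap=1000)
        c2 = train_csf_classifier(*args, seed=4, per_class_cap=1000)
        m1, _ = predict_csf(vol, masks["cranial"], c1)
        m2, _ = predict_csf(vol, masks["cranial"], c2)
        assert np.array_equal(m1.data, m2.data)

    def test_empty_truth_rejected(self):
        spec = PhantomSpec(seed=32)
        vol, masks = make_head_phantom(spec)
        empty = MaskVolume(np.zeros(vol.shape, dtype=bool), vol.spacing)
        with pytest.raises(DegenerateInputError):
            train_csf_classifier([(vol, masks["cranial"], empty)], seed=1)

    def test_prediction_respects_cranial_mask(self, default_phantom, trained_classifier):
        _, vol, masks = default_phantom
        mask, prob = predict_csf(vol, masks["cranial"], trained_classifier)
        assert not (mask.data & ~masks["cranial"].data).any()
        assert np.all(prob[~masks["cranial"].data] == 0.0)

    def test_threshold_extremes(self, default_phantom, trained_classifier):
        _, vol, masks = default_phantom
        all_in, prob = predict_csf(vol, masks["cranial"], trained_classifier, threshold=-0.01)
        none_in, _ = predict_csf(vol, masks["cranial"], trained_classifier, threshold=1.0)
        assert all_in.count() == masks["cranial"].count()
        assert none_in.count() == 0

    def test_bundle_roundtrip(self, tmp_path, default_phantom, trained_classifier):
        _, vol, masks = default_phantom
        save_classifier(trained_classifier, tmp_path / "bundle")
        back = load_classifier(tmp_path / "bundle")
        m1, _ = predict_csf(vol, masks["cranial"], trained_classifier)
        m2, _ = predict_csf(vol, masks["cranial"], back)
        assert np.array_equal(m1.data, m2.data)
        assert back.feature_spec == trained_classifier.feature_spec

    def test_forest_beats_threshold_under_infarct_confound(self, default_phantom, trained_classifier):
        _, vol, masks = default_phantom  # carries an 18-HU infarct
        rf, _ = predict_csf(vol, masks["cranial"], trained_classifier)
        thr = threshold_baseline_segment(vol, masks["cranial"], (0.0, 15.0))
        assert dice(rf, masks["csf"]) > dice(thr, masks["csf"])


class TestThresholdBaseline:
    def test_exact_on_noiseless_phantom_without_infarct(self, noiseless_phantom):
        _, vol, masks = noiseless_phantom
        thr = threshold_baseline_segment(vol, masks["cranial"], (0.0, 15.0))
        assert np.array_equal(thr.data, masks["csf"].data)

    def test_infarct_in_window_is_falsely_included(self):
        from edemascan.phantom import default_infarct

        spec = PhantomSpec(seed=33, noise_sd=0.0, infarct=default_infarct(), infarct_hu=12.0)
        vol, masks = make_head_phantom(spec)
        thr = threshold_baseline_segment(vol, masks["cranial"], (0.0, 15.0))
        assert (thr.data & masks["infarct"].data).sum() == masks["infarct"].count()

    def test_invalid_window(self, noiseless_phantom):
        _, vol, masks = noiseless_phantom
        with pytest.raises(ValueError):
            threshold_baseline_segment(vol, masks["cranial"], (15.0, 15.0))


class TestActiveContour:
    @staticmethod
    def two_region_sphere(noise=0.0, seed=0):
        X, Y, Z = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        sphere = ((X - 24) ** 2 + (Y - 24) ** 2 + (Z - 24) ** 2) <= 16**2
        img = np.where(sphere, 8.0, 32.0).astype(np.float32)
        if noise:
            img += np.random.default_rng(seed).normal(0, noise, img.shape).astype(np.float32)
        return CTVolume(img, (1, 1, 1)), MaskVolume(sphere, (1, 1, 1))

    def test_exact_truth_is_fixed_point(self):
        vol, truth = self.two_region_sphere()
        out = refine_active_contour(vol, truth, iterations=10, smoothing=1)
        changed = np.logical_xor(out.data, truth.data).sum() / truth.count()
        assert changed < 0.005

    def test_dilated_init_contracts_to_boundary(self):
        vol, truth = self.two_region_sphere(noise=2.0, seed=3)
        dil = MaskVolume(ndimage.binary_dilation(truth.data, iterations=2), vol.spacing)
        out = refine_active_contour(vol, dil, iterations=10, smoothing=1)
        assert dice(out, truth) > dice(dil, truth)

    def test_heavy_smoothing_never_grows_perimeter(self, rng):
        vol, truth = self.two_region_sphere()

        def perimeter(m):
            return int((m & ~ndimage.binary_erosion(m)).sum())

        cur = MaskVolume(truth.data | (rng.random(vol.shape) < 0.02), vol.spacing)
        perims = [perimeter(cur.data)]
        for _ in range(4):
            cur = refine_active_contour(vol, cur, iterations=1, smoothing=4)
            perims.append(perimeter(cur.data))
        assert all(b <= a for a, b in zip(perims, perims[1:]))

    def test_empty_init_rejected(self):
        vol, truth = self.two_region_sphere()
        with pytest.raises(DegenerateInputError):
            refine_active_contour(vol, MaskVolume(np.zeros(vol.shape, bool), vol.spacing))

    def test_result_confined_to_cranial(self, default_phantom, trained_classifier):
        _, vol, masks = default_phantom
        init, _ = predict_csf(vol, masks["cranial"], trained_classifier)
        out = refine_active_contour(vol, init, cranial=masks["cranial"], iterations=2)
        assert not (out.data & ~masks["cranial"].data).any()


class TestInfarctCleaning:
    def test_empty_infarct_is_identity(self, default_phantom):
        _, vol, masks = default_phantom
        empty = MaskVolume(np.zeros(vol.shape, bool), vol.spacing)
        assert np.array_equal(clean_with_infarct_mask(masks["csf"], empty).data, masks["csf"].data)

    def test_superset_infarct_annihilates(self, default_phantom):
        _, vol, masks = default_phantom
        full = MaskVolume(np.ones(vol.shape, bool), vol.spacing)
        assert clean_with_infarct_mask(masks["csf"], full).count() == 0

    def test_set_arithmetic(self):
        csf = np.zeros((10, 10, 3), bool)
        csf.ravel()[:100] = True
        inf = np.zeros_like(csf)
        inf.ravel()[70:100] = True
        out = clean_with_infarct_mask(MaskVolume(csf, (1, 1, 1)), MaskVolume(inf, (1, 1, 1)))
        assert out.count() == 70

    def test_grid_mismatch_rejected(self):
        a = MaskVolume(np.zeros((10, 10, 3), bool), (1, 1, 1))
        b = MaskVolume(np.zeros((10, 10, 4), bool), (1, 1, 1))
        with pytest.raises(GridMismatchError):
            clean_with_infarct_mask(a, b)
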