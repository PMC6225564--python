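import numpy as np
import pytest
from scipy import ndimage

from siftreg import Volume
from siftreg.sift3d import (
    DESCRIPTOR_LENGTH,
    DegenerateInputError,
    VolumeTooSmallError,
    build_scale_space,
    compute_descriptors,
    detect_keypoints,
    extract_features,
    normalize_intensities,
)

from conftest import make_blob_volume


class TestNormalize:
    def test_spanning_volume_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (12, 12, 12))
        data.flat[0], data.flat[1] = 0.0, 1.0
        vol = Volume(data)
        out = normalize_intensities(vol, lower_percentile=0, upper_percentile=100)
        assert np.allclose(out.data, data, atol=1e-6)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.standard_normal((16, 16, 16)))
        mapped = vol.with_data(3.5 * vol.data + 100.0)
        a = normalize_intensities(vol).data
        b = normalize_intensities(mapped).data
        assert np.allclose(a, b, atol=1e-6)

    def test_constant_volume_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize_intensities(Volume(np.full((8, 8, 8), 3.0)))


class TestScaleSpace:
    def test_geometric_sigma_schedule(self):
        vol = Volume(np.random.default_rng(2).random((48, 48, 48)))
        ss = build_scale_space(vol, levels_per_octave=3, sigma0_mm=1.6)
        sig = ss.octaves[0].sigmas_mm
        k = 2.0 ** (1.0 / 3.0)
        assert np.allclose(sig[1:] / sig[:-1], k, rtol=1e-12)
        # next octave starts at doubled sigma and doubled spacing
        assert np.isclose(ss.octaves[1].sigmas_mm[0], 2 * sig[0])
        assert np.allclose(ss.octaves[1].spacing, 2 * ss.octaves[0].spacing)

    def test_dog_of_constant_volume_is_zero(self):
        vol = Volume(np.full((32, 32, 32), 7.0))
        ss = build_scale_space(vol)
        for octave in ss.octaves:
            for dog in octave.dogs:
                assert np.allclose(dog, 0.0, atol=1e-5)

    def test_incremental_blur_matches_direct_blur(self):
        # level i of octave 0 must equal one direct smoothing of level 0
        # with sqrt(sigma_i^2 - sigma_0^2): the Gaussian semigroup property
        # applied to our incremental construction.
        rng = np.random.default_rng(3)
        vol = Volume(rng.standard_normal((32, 32, 32)))
        ss = build_scale_space(vol, levels_per_octave=3, sigma0_mm=1.6)
        oct0 = ss.octaves[0]
        h = oct0.spacing[0]
        # sampled discrete Gaussian kernels obey the semigroup property only
        # approximately at sigma ~ 1 voxel; white noise is the worst case and
        # the discrepancy accumulates with each incremental step
        for i in (2, 3):
            inc = np.sqrt(oct0.sigmas_mm[i] ** 2 - oct0.sigmas_mm[0] ** 2) / h
            direct = ndimage.gaussian_filter(oct0.gaussians[0], inc, mode="nearest")
            rms = np.sqrt(np.mean((direct - oct0.gaussians[i]) ** 2))
            assert rms < 5e-3

    def test_too_small_volume_names_axis(self):
        vol = Volume(np.zeros((64, 64, 6)))
        with pytest.raises(VolumeTooSmallError) as exc:
            build_scale_space(vol, n_octaves=1)
        assert "z" in str(exc.value)

    def test_anisotropic_grid_rejected(self):
        vol = Volume(np.zeros((32, 32, 32)), spacing=(1.0, 1.0, 3.0))
        with pytest.raises(ValueError):
            build_scale_space(vol)


class TestDetect:
    def test_uniform_volume_has_no_keypoints(self):
        ss = build_scale_space(Volume(np.zeros((48, 48, 48))))
        assert len(detect_keypoints(ss)) == 0

    def test_single_blob_detected_at_center_and_scale(self):
        center = np.array([30.3, 32.5, 29.8])
        sigma_blob = 4.0
        vol = make_blob_volume((64, 64, 64), center, sigma_blob, 1.0)
        ss = build_scale_space(vol)
        kps = detect_keypoints(ss, contrast_threshold=0.005)
        assert len(kps) >= 1
        strongest = int(np.argmax(np.abs(kps.responses)))
        assert np.linalg.norm(kps.positions[strongest] - center) <= 1.0  # 1 voxel @ 1 mm
        # Closed-form oracle: for a 3D Gaussian blob of width s, the DoG
        # center response is proportional to sigma^2 * (s^2 + sigma^2)^(-5/2),
        # which peaks at sigma = sqrt(2/3) * s (in 2D the peak is at s).
        expected_scale = np.sqrt(2.0 / 3.0) * sigma_blob
        ratio = kps.scales[strongest] / expected_scale
        assert 2 ** (-1 / 3) <= ratio <= 2 ** (1 / 3)

    def test_translation_covariance(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(18, 40, (6, 3))
        sigmas = rng.uniform(2.5, 5.0, 6)
        vol = make_blob_volume((64, 64, 64), centers, sigmas, np.ones(6))
        shift = np.array([3, -2, 5])
        vol_shifted = make_blob_volume((64, 64, 64), centers + shift, sigmas, np.ones(6))
        kp_a = detect_keypoints(build_scale_space(vol), contrast_threshold=0.005)
        kp_b = detect_keypoints(build_scale_space(vol_shifted), contrast_threshold=0.005)
        assert len(kp_a) and len(kp_b)
        # every strong keypoint of A must have a partner at position + shift
        for pos in kp_a.positions:
            d = np.linalg.norm(kp_b.positions - (pos + shift), axis=1)
            assert d.min() <= 0.5

    def test_max_features_cap_keeps_strongest(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(15, 45, (12, 3))
        vol = make_blob_volume((60, 60, 60), centers, rng.uniform(2, 4, 12), rng.uniform(0.3, 1, 12))
        ss = build_scale_space(vol)
        full = detect_keypoints(ss, contrast_threshold=0.005)
        capped = detect_keypoints(ss, contrast_threshold=0.005, max_features=3)
        assert len(capped) == 3
        top = np.sort(np.abs(full.responses))[-3:]
        assert np.allclose(np.sort(np.abs(capped.responses)), top)


class TestDescriptors:
    @pytest.fixture(scope="class")
    def textured(self):
        rng = np.random.default_rng(6)
        centers = rng.uniform(12, 52, (40, 3))
        sigmas = rng.uniform(2.0, 5.0, 40)
        amps = rng.uniform(0.3, 1.0, 40)
        return make_blob_volume((64, 64, 64), centers, sigmas, amps, noise_rng=rng)

    def test_unit_norm_or_zero(self, textured):
        ss = build_scale_space(textured)
        fs = compute_descriptors(ss, detect_keypoints(ss, contrast_threshold=0.003))
        assert len(fs) > 0
        assert fs.descriptors.shape[1] == DESCRIPTOR_LENGTH
        norms = np.linalg.norm(fs.descriptors, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-6) | (norms == 0))
        assert np.all(fs.descriptors >= 0)

    def test_determinism(self, textured):
        a = extract_features(textured, working_spacing=1.0)
        b = extract_features(textured, working_spacing=1.0)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_matching_margin_under_translation(self, textured):
        shift_vox = np.array([5, 0, 0])
        shifted = Volume(np.roll(textured.data, shift_vox, axis=(0, 1, 2)),
                         textured.spacing, textured.origin, textured.direction)
        fa = extract_features(textured, working_spacing=1.0, contrast_threshold=0.003)
        fb = extract_features(shifted, working_spacing=1.0, contrast_threshold=0.003)
        # pair keypoints by ground-truth geometry; skip keypoints whose
        # descriptor window (about 6 sigma) reaches the np.roll wrap-around
        checked = 0
        for i, pos in enumerate(fa.positions):
            target = pos + shift_vox
            margin = 6.0 * fa.scales[i] + 2.0
            lo, hi = margin, 64.0 - margin
            if np.any(pos < lo) or np.any(pos > hi) or np.any(target < lo) or np.any(target > hi):
                continue
            d = np.linalg.norm(fb.positions - target, axis=1)
            j = int(np.argmin(d))
            if d[j] > 1.0:
                continue
            dist = np.linalg.norm(fb.descriptors - fa.descriptors[i], axis=1)
            order = np.argsort(dist)
            if order[0] != j:
                continue
            assert dist[j] < 0.3
            assert dist[order[1]] > dist[j]
            checked += 1
        assert checked >= 5

    def test_intensity_invariance_end_to_end(self, textured):
        remapped = textured.with_data(2.0 * textured.data + 5.0)
        fa = extract_features(textured, working_spacing=1.0)
        fb = extract_features(remapped, working_spacing=1.0)
        assert len(fa) == len(fb)
        assert np.all(np.linalg.norm(fa.positions - fb.positions, axis=1) < 0.5)
        assert np.all(np.linalg.norm(fa.descriptors - fb.descriptors, axis=1) < 1e-3)


def test_feature_count_order_of_thousands():
    """A textured body-sized phantom yields features 'in the order of few
    thousands' at default thresholds."""
    rng = np.random.default_rng(7)
    data = ndimage.gaussian_filter(rng.standard_normal((128, 128, 128)), 2.0)
    centers = rng.uniform(20, 236, (60, 3))
    vol = make_blob_volume((128, 128, 128), centers, rng.uniform(3, 9, 60),
                           rng.uniform(2, 6, 60), spacing=2.0)
    vol = vol.with_data(vol.data + 0.8 * data / data.std())
    fs = extract_features(vol)
    assert 500 <= len(fs) <= 50000


def test_featureset_csv_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    vol = make_blob_volume((48, 48, 48), rng.uniform(12, 36, (10, 3)),
                           rng.uniform(2, 4, 10), np.ones(10))
    fs = extract_features(vol, working_spacing=1.0, contrast_threshold=0.003)
    assert len(fs) > 0
    path = tmp_path / "features.csv"
    fs.to_csv(path)
    back = type(fs).from_csv(path)
    assert np.allclose(back.positions, fs.positions, atol=1e-6)
    assert np.allclose(back.descriptors, fs.descriptors, atol=1e-12)
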