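"""Container, I/O, resampling, sampling and warping contracts."""

import numpy as np
import pytest

from bmdir import (BinaryMask, DisplacementField, ImageVolume, LandmarkSet,
                   read_landmarks, read_volume, resample, sample_dvf,
                   warp_image, warp_mask, write_landmarks, write_volume)
from conftest import affine_field, smooth_test_image


class TestRoundTrip:
    def test_image_roundtrip_nifti(self, tmp_path, rng):
        vol = ImageVolume(rng.standard_normal((4, 4, 4)), (0.5, 0.5, 2.0),
                          (1.0, -2.0, 3.0))
        p = tmp_path / "img.nii.gz"
        write_volume(vol, p)
        back = read_volume(p, kind="image")
        np.testing.assert_array_almost_equal(back.voxels, vol.voxels, decimal=6)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)

    def test_image_roundtrip_nrrd(self, tmp_path, rng):
        vol = ImageVolume(rng.standard_normal((5, 4, 6)), (1.0, 1.0, 1.0))
        p = tmp_path / "img.nrrd"
        write_volume(vol, p)
        back = read_volume(p, kind="image")
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=1e-6)

    def test_dvf_roundtrip(self, tmp_path, rng):
        dvf = DisplacementField(rng.standard_normal((4, 5, 6, 3)),
                                (0.5, 0.5, 2.0))
        p = tmp_path / "dvf.nii.gz"
        write_volume(dvf, p)
        back = read_volume(p, kind="dvf")
        assert isinstance(back, DisplacementField)
        assert back.voxels.shape == (4, 5, 6, 3)
        assert np.all(np.isfinite(back.voxels))
        np.testing.assert_allclose(back.voxels, dvf.voxels, atol=1e-6)

    def test_mask_roundtrip_and_nonbinary_error(self, tmp_path, rng):
        m = BinaryMask(rng.integers(0, 2, (4, 4, 4)), (1, 1, 1))
        p = tmp_path / "m.nii.gz"
        write_volume(m, p)
        assert np.array_equal(read_volume(p, kind="mask").voxels, m.voxels)
        bad = ImageVolume(np.full((4, 4, 4), 2.0), (1, 1, 1))
        pb = tmp_path / "bad.nii.gz"
        write_volume(bad, pb)
        with pytest.raises(ValueError):
            read_volume(pb, kind="mask")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_landmark_csv_roundtrip(self, tmp_path, rng):
        lms = LandmarkSet(rng.uniform(0, 10, (6, 3)), rng.uniform(0, 10, (6, 3)),
                          [f"L{i}" for i in range(6)])
        p = tmp_path / "lm.csv"
        write_landmarks(lms, p)
        back = read_landmarks(p)
        np.testing.assert_allclose(back.fixed, lms.fixed)
        np.testing.assert_allclose(back.moving, lms.moving)
        assert back.labels == lms.labels


class TestInvariants:
    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((3, 3, 3)), (1.0, 0.0, 1.0))

    def test_dvf_must_be_finite(self):
        v = np.zeros((3, 3, 3, 3))
        v[1, 1, 1, 0] = np.nan
        with pytest.raises(ValueError):
            DisplacementField(v, (1, 1, 1))

    def test_physical_coordinates(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), (0.5, 1.0, 2.0), (10, 20, 30))
        np.testing.assert_allclose(vol.index_to_physical([2, 3, 1]),
                                   [11.0, 23.0, 32.0])
        np.testing.assert_allclose(vol.physical_to_index([11.0, 23.0, 32.0]),
                                   [2, 3, 1])


class TestResample:
    def test_constant_stays_constant(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.7), (1, 1, 1))
        out = resample(vol, (0.6, 1.3, 2.0))
        np.testing.assert_allclose(out.voxels, 3.7)

    def test_identity(self, rng):
        vol = ImageVolume(rng.standard_normal((6, 6, 6)), (1, 1, 1))
        out = resample(vol, (1, 1, 1))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_linear_ramp_reproduced_2x_finer(self):
        nx = 8
        x = np.arange(nx)[:, None, None] * np.ones((1, 8, 8))
        vol = ImageVolume(x, (2.0, 2.0, 2.0))  # I(x) = x_mm / 2
        out = resample(vol, (1.0, 1.0, 1.0))
        pts_x = np.arange(out.shape[0]) * 1.0
        expected = pts_x / 2.0
        got = out.voxels[:, 4, 4]
        np.testing.assert_allclose(got[:-1], expected[:-1], atol=1e-6)

    def test_extent_preserved_within_one_voxel(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        out = resample(vol, (0.7, 0.7, 0.7))
        old_extent = 9.0
        new_extent = (np.array(out.shape) - 1) * 0.7
        assert np.all(np.abs(new_extent - old_extent) <= 0.7)

    def test_mask_resample_threshold(self):
        m = np.zeros((10, 10, 10))
        m[3:7, 3:7, 3:7] = 1
        mask = BinaryMask(m, (1, 1, 1))
        out = resample(mask, (0.5, 0.5, 0.5))
        assert isinstance(out, BinaryMask)
        assert set(np.unique(out.voxels)) <= {0, 1}
        assert out.count > 0

    def test_degenerate_spacing_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            resample(vol, (1, -1, 1))


class TestSampleDvf:
    def test_constant_field(self, rng):
        v = np.tile([1.0, 2.0, 3.0], (5, 5, 5, 1))
        dvf = DisplacementField(v, (1, 1, 1))
        pts = rng.uniform(0, 4, (20, 3))
        np.testing.assert_allclose(sample_dvf(dvf, pts),
                                   np.tile([1, 2, 3], (20, 1)))

    def test_voxel_center_bit_exact(self, rng):
        v = rng.standard_normal((5, 5, 5, 3))
        dvf = DisplacementField(v, (0.5, 0.5, 2.0), (1, 2, 3))
        pt = dvf.index_to_physical([2, 3, 1])
        np.testing.assert_array_equal(sample_dvf(dvf, [pt])[0], v[2, 3, 1])

    def test_affine_field_reproduced(self, rng):
        vol = ImageVolume(np.zeros((9, 9, 9)), (1.5, 1.0, 0.5), (2, -1, 0))
        A = rng.uniform(-0.1, 0.1, (3, 3))
        b = rng.uniform(-1, 1, 3)
        dvf = affine_field(vol, A, b)
        lo = vol.index_to_physical([1, 1, 1])
        hi = vol.index_to_physical([7, 7, 7])
        pts = rng.uniform(lo, hi, (100, 3))
        expected = pts @ A.T + b
        np.testing.assert_allclose(sample_dvf(dvf, pts), expected, atol=1e-9)

    def test_nan_rejected(self):
        v = np.zeros((3, 3, 3, 3))
        dvf = DisplacementField(v, (1, 1, 1))
        dvf.voxels[0, 0, 0, 0] = np.nan  # bypass constructor check
        with pytest.raises(ValueError):
            sample_dvf(dvf, [[1.0, 1.0, 1.0]])

    def test_out_of_bounds_clamped(self):
        v = np.tile([1.0, 0, 0], (4, 4, 4, 1))
        v[0] = [5.0, 0, 0]
        dvf = DisplacementField(v, (1, 1, 1))
        np.testing.assert_allclose(sample_dvf(dvf, [[-10, 1, 1]])[0],
                                   [5.0, 0, 0])


class TestWarp:
    def test_zero_dvf_is_identity(self, rng):
        img = smooth_test_image()
        dvf = DisplacementField(np.zeros(img.shape + (3,)), img.spacing)
        out = warp_image(img, dvf)
        np.testing.assert_allclose(out.voxels, img.voxels, atol=1e-12)

    def test_translation_recovers_reference(self):
        # image std is 50; tolerances are double-trilinear interpolation error
        img = smooth_test_image(shape=(24, 24, 24), sigma=4.0)
        t = np.array([1.3, -0.7, 0.4])
        # moving(y) = reference(y - t): sample the reference on a shifted grid
        moving = ImageVolume(np.zeros(img.shape), img.spacing)
        pts = moving.voxel_centers() - t
        from bmdir.grids import _sample_scalar
        moving.voxels = _sample_scalar(img, pts, mode="nearest")
        dvf = DisplacementField(np.tile(t, img.shape + (1,)), img.spacing)
        out = warp_image(moving, dvf)
        core = (slice(3, -3),) * 3
        err = np.abs(out.voxels[core] - img.voxels[core])
        rms = np.sqrt((err ** 2).mean())
        assert rms < 0.03 * img.voxels.std() and err.max() < 0.12 * img.voxels.std()

    def test_fully_out_of_bounds_gives_fill(self):
        img = smooth_test_image(shape=(8, 8, 8))
        dvf = DisplacementField(np.full(img.shape + (3,), 100.0), img.spacing)
        out = warp_image(img, dvf, fill_value=-1.0)
        np.testing.assert_allclose(out.voxels, -1.0)

    def test_warp_mask_zero_dvf(self):
        m = np.zeros((10, 10, 10))
        m[3:7, 3:7, 3:7] = 1
        mask = BinaryMask(m, (1, 1, 1))
        dvf = DisplacementField(np.zeros((10, 10, 10, 3)), (1, 1, 1))
        assert np.array_equal(warp_mask(mask, dvf).voxels, mask.voxels)

    def test_warp_mask_lattice_translation_exact(self):
        m = np.zeros((12, 12, 12))
        m[2:6, 2:6, 2:6] = 1
        mask = BinaryMask(m, (0.5, 0.5, 0.5))
        # pull-back by exactly +2 voxels along x: output(i) = input(i+2)
        dvf = DisplacementField(np.tile([1.0, 0, 0], (12, 12, 12, 1)),
                                (0.5, 0.5, 0.5))
        out = warp_mask(mask, dvf)
        expected = np.zeros_like(m)
        expected[0:4, 2:6, 2:6] = 1
        assert np.array_equal(out.voxels, expected)

    def test_warp_mask_half_voxel_translation_count(self):
        m = np.zeros((14, 14, 14))
        m[2:12, 2:12, 2:12] = 1  # a 10^3 cube
        mask = BinaryMask(m, (1, 1, 1))
        dvf = DisplacementField(np.tile([0.5, 0, 0], (14, 14, 14, 1)), (1, 1, 1))
        out = warp_mask(mask, dvf)
        # brute-force count: the 0.5-threshold keeps 10 or 11 x-layers
        assert abs(out.count - 1000) <= 100  # within one voxel layer of 10^3
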