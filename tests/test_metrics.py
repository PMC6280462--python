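"""Evaluation battery vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from bmdir import (BinaryMask, DisplacementField, ImageVolume, LandmarkSet,
                   dice, jacobian_map, surface_distances, trd, tre)
from bmdir.metrics import boundary_voxels
from conftest import affine_field


def random_mask(rng, shape=(20, 20, 20), spacing=(1, 1, 1)):
    """A random connected-ish nonempty blob mask."""
    from scipy import ndimage
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
    m = field > np.quantile(field, 0.8)
    if not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return BinaryMask(m, spacing)


def brute_surface_distances(a: BinaryMask, b: BinaryMask):
    """O(n^2) pairwise oracle for Hausdorff / mean surface distance."""
    sp = np.array(a.spacing)
    pa = boundary_voxels(a) * sp
    pb = boundary_voxels(b) * sp
    D = cdist(pa, pb)
    d_ab = D.min(axis=1)
    d_ba = D.min(axis=0)
    return max(d_ab.max(), d_ba.max()), 0.5 * (d_ab.mean() + d_ba.mean())


class TestDice:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8)); a[:2] = 1
        b = np.zeros((8, 8, 8)); b[6:] = 1
        assert dice(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) == 0.0

    def test_half_overlapping_cubes(self):
        a = np.zeros((8, 8, 8)); a[0:4, 0:4, 0:4] = 1
        b = np.zeros((8, 8, 8)); b[2:6, 0:4, 0:4] = 1
        # overlap is a 2x4x4 slab: 2*32/(64+64) = 0.5
        assert dice(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) == 0.5

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_rejected(self):
        e = BinaryMask(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            dice(e, e)

    def test_grid_mismatch_rejected(self, rng):
        a = random_mask(rng)
        b = BinaryMask(a.voxels, (2, 1, 1))
        with pytest.raises(ValueError):
            dice(a, b)


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        hd, msd = surface_distances(m, m)
        assert hd == 0.0 and msd == 0.0

    def test_single_voxels_spacing_aware(self):
        a = np.zeros((10, 10, 10)); a[2, 5, 5] = 1
        b = np.zeros((10, 10, 10)); b[5, 5, 5] = 1
        hd, msd = surface_distances(BinaryMask(a, (0.5, 0.5, 0.5)),
                                    BinaryMask(b, (0.5, 0.5, 0.5)))
        assert hd == pytest.approx(1.5, abs=1e-12)
        assert msd == pytest.approx(1.5, abs=1e-12)

    def test_against_brute_force(self, rng):
        for _ in range(25):
            a, b = random_mask(rng), random_mask(rng)
            hd, msd = surface_distances(a, b)
            bhd, bmsd = brute_surface_distances(a, b)
            assert hd == pytest.approx(bhd, abs=1e-9)
            assert msd == pytest.approx(bmsd, abs=1e-9)

    def test_hausdorff_ge_msd(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            hd, msd = surface_distances(a, b)
            assert hd >= msd >= 0

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            surface_distances(random_mask(rng),
                              BinaryMask(np.zeros((20, 20, 20)), (1, 1, 1)))


class TestJacobian:
    def test_zero_field(self):
        dvf = DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        j = jacobian_map(dvf)
        np.testing.assert_allclose(j["map"], 1.0, atol=1e-15)

    def test_translation_field(self):
        dvf = DisplacementField(np.tile([2.0, -1.0, 0.5], (8, 8, 8, 1)), (1, 1, 1))
        np.testing.assert_allclose(jacobian_map(dvf)["map"], 1.0, atol=1e-15)

    def test_uniform_dilation(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
        dvf = affine_field(vol, 0.1 * np.eye(3), np.zeros(3))
        j = jacobian_map(dvf)["map"]
        interior = j[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 1.1 ** 3, atol=1e-9)

    def test_translation_composition_invariance(self, rng):
        vol = ImageVolume(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
        A = rng.uniform(-0.05, 0.05, (3, 3))
        base = affine_field(vol, A, np.zeros(3))
        shifted = DisplacementField(base.voxels + np.array([3.0, -2.0, 1.0]),
                                    base.spacing)
        np.testing.assert_allclose(jacobian_map(shifted)["map"],
                                   jacobian_map(base)["map"], atol=1e-12)

    def test_grid_too_small_rejected(self):
        dvf = DisplacementField(np.zeros((2, 8, 8, 3)), (1, 1, 1))
        with pytest.raises(ValueError):
            jacobian_map(dvf)


class TestTrd:
    def test_identical_fields(self, rng):
        v = rng.standard_normal((8, 8, 8, 3))
        dvf = DisplacementField(v, (1, 1, 1))
        res = trd(dvf, dvf)
        assert np.abs(res["map"]).max() == 0.0
        assert all(v == 0.0 for v in res["frac_above"].values())

    def test_constant_offset(self):
        a = DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        b = DisplacementField(np.tile([3.0, 0, 0], (8, 8, 8, 1)), (1, 1, 1))
        res = trd(a, b)
        np.testing.assert_allclose(res["map"], 3.0)
        assert res["frac_above"][1.5] == 1.0
        assert res["frac_above"][2.0] == 1.0

    def test_fractions_match_counting_oracle(self, rng):
        a = DisplacementField(rng.standard_normal((12, 12, 12, 3)), (1, 1, 1))
        b = DisplacementField(rng.standard_normal((12, 12, 12, 3)), (1, 1, 1))
        mask = random_mask(rng, shape=(12, 12, 12))
        res = trd(a, b, mask, thresholds_mm=(0.5, 1.0, 2.0))
        d = np.linalg.norm(a.voxels - b.voxels, axis=-1)[mask.voxels.astype(bool)]
        for t in (0.5, 1.0, 2.0):
            assert res["frac_above"][t] == pytest.approx(np.mean(d > t), abs=1e-12)

    def test_cumulative_histogram_monotone(self, rng):
        a = DisplacementField(rng.standard_normal((10, 10, 10, 3)), (1, 1, 1))
        b = DisplacementField(rng.standard_normal((10, 10, 10, 3)), (1, 1, 1))
        res = trd(a, b)
        assert np.all(np.diff(res["cumulative"]) >= 0)
        ts = sorted(res["frac_above"])
        fracs = [res["frac_above"][t] for t in ts]
        assert all(y <= x for x, y in zip(fracs, fracs[1:]))


class TestProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_dice_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_mask(r, shape=(12, 12, 12)), random_mask(r, shape=(12, 12, 12))
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_permuting_both_masks_preserves_dice(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_mask(r, shape=(12, 12, 12)), random_mask(r, shape=(12, 12, 12))
        perm = r.permutation(12)
        ap = BinaryMask(a.voxels[perm], a.spacing)
        bp = BinaryMask(b.voxels[perm], b.spacing)
        assert dice(ap, bp) == dice(a, b)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_trd_fraction_non_increasing_in_threshold(self, seed):
        r = np.random.default_rng(seed)
        a = DisplacementField(r.standard_normal((8, 8, 8, 3)), (1, 1, 1))
        b = DisplacementField(r.standard_normal((8, 8, 8, 3)), (1, 1, 1))
        ts = np.sort(r.uniform(0.1, 4.0, 4))
        res = trd(a, b, thresholds_mm=ts)
        fracs = [res["frac_above"][float(t)] for t in ts]
        assert all(0 <= f <= 1 for f in fracs)
        assert all(y <= x for x, y in zip(fracs, fracs[1:]))


class TestTre:
    def test_exact_field_gives_zero(self, rng):
        vol = ImageVolume(np.zeros((12, 12, 12)), (1, 1, 1))
        fixed = rng.uniform(2, 9, (5, 3))
        disp = np.tile([1.0, -0.5, 0.25], (5, 1))
        dvf = DisplacementField(np.tile([1.0, -0.5, 0.25], (12, 12, 12, 1)),
                                (1, 1, 1))
        lms = LandmarkSet(fixed, fixed + disp)
        res = tre(lms, dvf)
        assert res["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_dvf_equals_separation(self, rng):
        fixed = rng.uniform(2, 9, (5, 3))
        moving = fixed + rng.uniform(-1, 1, (5, 3))
        dvf = DisplacementField(np.zeros((12, 12, 12, 3)), (1, 1, 1))
        lms = LandmarkSet(fixed, moving)
        res = tre(lms, dvf)
        expected = np.linalg.norm(fixed - moving, axis=1)
        np.testing.assert_allclose(list(res["per_landmark"].values()), expected,
                                   atol=1e-12)
        assert res["mean"] == pytest.approx(expected.mean())
        assert res["sd"] == pytest.approx(expected.std())

    def test_affine_consistency(self, rng):
        vol = ImageVolume(np.zeros((12, 12, 12)), (1, 1, 1))
        A = rng.uniform(-0.05, 0.05, (3, 3))
        b = rng.uniform(-0.5, 0.5, 3)
        dvf = affine_field(vol, A, b)
        fixed = rng.uniform(2, 9, (6, 3))
        moving = fixed + fixed @ A.T + b
        res = tre(LandmarkSet(fixed, moving), dvf)
        assert res["mean"] < 1e-6

    def test_landmark_outside_grid_rejected(self):
        dvf = DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1))
        lms = LandmarkSet([[100.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(ValueError):
            tre(lms, dvf)
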