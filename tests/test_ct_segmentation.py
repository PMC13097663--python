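import itertools

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_otsu

from morphodiverge.ct_segmentation import (
    BinaryVolume,
    GreyVolume,
    ThresholdSpec,
    erode_binary,
    global_halfmax_threshold,
    local_otsu,
    otsu_vote_segmentation,
    reslice,
    reslice_inverse,
    segmentation_compare,
    vote_combine,
)
from morphodiverge.errors import ValidationError
from morphodiverge.synthetic_data import (
    PhantomParams,
    default_phantom_params,
    simulate_phantom,
)


def ball_mask(shape, center, radius):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


class TestErodeBinary:
    def test_radius_zero_is_identity(self, rng):
        m = BinaryVolume(rng.random((6, 6, 6)) > 0.5)
        out = erode_binary(m, 0)
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_single_voxel_radius_one_empty(self):
        v = np.zeros((5, 5, 5), bool)
        v[2, 2, 2] = True
        assert erode_binary(BinaryVolume(v), 1).count() == 0

    def test_ball_erosion_matches_distance_oracle(self):
        shape = (25, 25, 25)
        ball = ball_mask(shape, (12, 12, 12), 10)
        out = erode_binary(BinaryVolume(ball), 3)
        # brute-force oracle: voxels whose distance to the nearest outside
        # voxel exceeds the radius
        outside = np.argwhere(~ball)
        inside = np.argwhere(ball)
        keep = np.zeros(len(inside), bool)
        for i, p in enumerate(inside):
            d2 = ((outside - p) ** 2).sum(axis=1).min()
            keep[i] = d2 > 9
        assert out.count() == int(keep.sum())


class TestHalfMax:
    def test_constant_seeds_exact_threshold(self):
        vox = np.full((8, 8, 8), 100.0)
        bone = np.zeros((8, 8, 8), bool)
        bone[:4] = True
        vox[bone] = 200.0
        spec, seg = global_halfmax_threshold(
            GreyVolume(vox), BinaryVolume(bone), BinaryVolume(~bone),
            shrink_bone=0, shrink_background=0,
        )
        assert spec.threshold == 150.0
        np.testing.assert_array_equal(seg.voxels, bone)

    def test_phantom_threshold_and_accuracy(self):
        vol, truth = simulate_phantom(default_phantom_params(seed=4))
        spec, seg = global_halfmax_threshold(
            vol, truth, BinaryVolume(~truth.voxels), shrink_bone=3, shrink_background=3
        )
        assert abs(spec.threshold - 120.0) < 2.0
        assert (seg.voxels == truth.voxels).mean() >= 0.99

    def test_inverted_means_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdSpec(mean_bone=50.0, mean_background=100.0)

    def test_overshrunk_seed_reports_radius(self):
        vol, truth = simulate_phantom(default_phantom_params(seed=4))
        with pytest.raises(ValidationError, match="background"):
            global_halfmax_threshold(
                vol, truth, BinaryVolume(~truth.voxels),
                shrink_bone=3, shrink_background=60,
            )

    def test_threshold_monotone(self):
        vol, _ = simulate_phantom(default_phantom_params(seed=5))
        low = vol.voxels >= 100.0
        high = vol.voxels >= 140.0
        assert not (high & ~low).any()


class TestLocalOtsu:
    def test_step_image_matches_global_otsu(self):
        # every neighborhood contains the two-level step
        img = np.where(np.arange(32)[None, :] < 16, 60.0, 180.0)
        img = np.tile(img, (32, 1))
        vol = GreyVolume(np.stack([img] * 3))
        out = local_otsu(vol, radius=5)
        t = threshold_otsu(img.astype(np.uint8))
        np.testing.assert_array_equal(out.voxels[0], img > t)

    def test_constant_volume_all_background(self):
        out = local_otsu(GreyVolume(np.full((4, 20, 20), 7.0)), radius=5)
        assert out.count() == 0

    def test_phantom_slice_accuracy(self):
        vol, truth = simulate_phantom(default_phantom_params(seed=6))
        out = local_otsu(vol, radius=5)
        assert (out.voxels == truth.voxels).mean() >= 0.98


class TestReslice:
    def test_original_is_identity(self, rng):
        v = GreyVolume(rng.random((3, 4, 5)))
        np.testing.assert_array_equal(reslice(v, "original").voxels, v.voxels)

    @pytest.mark.parametrize("orientation", ["original", "top_bottom", "left_right"])
    def test_inverse_round_trip(self, orientation, rng):
        v = GreyVolume(rng.random((3, 4, 5)), spacing=(1.0, 2.0, 3.0))
        back = reslice_inverse(reslice(v, orientation), orientation)
        np.testing.assert_array_equal(back.voxels, v.voxels)
        assert back.spacing == v.spacing

    def test_labeled_array_mapping(self):
        v = GreyVolume(np.arange(24, dtype=float).reshape(2, 3, 4))
        tb = reslice(v, "top_bottom")
        assert tb.shape == (3, 2, 4)
        assert tb.voxels[1, 0, 2] == v.voxels[0, 1, 2]
        lr = reslice(v, "left_right")
        assert lr.shape == (4, 2, 3)
        assert lr.voxels[3, 1, 2] == v.voxels[1, 2, 3]

    def test_unknown_orientation(self, rng):
        with pytest.raises(ValidationError):
            reslice(GreyVolume(rng.random((2, 2, 2))), "diagonal")


class TestVote:
    def test_exhaustive_truth_table(self):
        for bits in itertools.product([False, True], repeat=3):
            masks = [BinaryVolume(np.full((1, 1, 1), b)) for b in bits]
            out = vote_combine(*masks)
            assert out.voxels[0, 0, 0] == (sum(bits) >= 2)

    def test_identical_inputs_pass_through(self, rng):
        m = BinaryVolume(rng.random((4, 4, 4)) > 0.5)
        np.testing.assert_array_equal(vote_combine(m, m, m).voxels, m.voxels)

    def test_matches_brute_force_on_random_volumes(self, rng):
        a, b, c = (BinaryVolume(rng.random((50, 50, 40)) > 0.5) for _ in range(3))
        out = vote_combine(a, b, c)
        brute = (
            a.voxels.astype(int) + b.voxels.astype(int) + c.voxels.astype(int)
        ) >= 2
        np.testing.assert_array_equal(out.voxels, brute)

    def test_permutation_invariant(self, rng):
        a, b, c = (BinaryVolume(rng.random((5, 5, 5)) > 0.5) for _ in range(3))
        ref = vote_combine(a, b, c).voxels
        for p in itertools.permutations([a, b, c]):
            np.testing.assert_array_equal(vote_combine(*p).voxels, ref)

    def test_shape_mismatch(self, rng):
        a = BinaryVolume(np.zeros((2, 2, 2), bool))
        b = BinaryVolume(np.zeros((3, 2, 2), bool))
        with pytest.raises(ValidationError):
            vote_combine(a, a, b)


class TestSegmentationCompare:
    def test_identical_masks(self, rng):
        m = BinaryVolume(ball_mask((12, 12, 12), (6, 6, 6), 4))
        rep = segmentation_compare(m, m)
        assert rep == {
            "disagreement_voxels": 0,
            "dice": 1.0,
            "max_boundary_distance": 0.0,
        }

    def test_one_voxel_dilation_shell(self):
        m = ball_mask((16, 16, 16), (8, 8, 8), 4)
        dil = ndimage.binary_dilation(m)
        rep = segmentation_compare(BinaryVolume(m), BinaryVolume(dil))
        assert rep["max_boundary_distance"] == pytest.approx(1.0)
        assert rep["disagreement_voxels"] == int((dil & ~m).sum())

    def test_disjoint_masks_dice_zero(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        rep = segmentation_compare(BinaryVolume(a), BinaryVolume(b))
        assert rep["dice"] == 0.0


class TestProtocolAgreement:
    def test_halfmax_and_otsu_vote_agree_near_boundary_only(self):
        vol, truth = simulate_phantom(default_phantom_params(shape=(64, 64, 64), seed=2))
        _, seg = global_halfmax_threshold(
            vol, truth, BinaryVolume(~truth.voxels), shrink_bone=3, shrink_background=3
        )
        ov = otsu_vote_segmentation(vol)
        dis = seg.voxels ^ ov.voxels
        assert dis.mean() < 0.01
        if dis.any():
            db = np.where(
                truth.voxels,
                ndimage.distance_transform_edt(truth.voxels),
                ndimage.distance_transform_edt(~truth.voxels),
            )
            assert db[dis].max() <= 2.0


class TestPhantomGenerator:
    def test_noiseless_phantom_separates_exactly(self):
        p = default_phantom_params(shape=(32, 32, 32), seed=0, noise_sd=0.0)
        vol, truth = simulate_phantom(p)
        seg = vol.voxels >= 120.0
        np.testing.assert_array_equal(seg, truth.voxels)

    def test_empty_geometry_all_background(self):
        vol, truth = simulate_phantom(PhantomParams(shape=(8, 8, 8), seed=1))
        assert truth.count() == 0

    def test_geometry_exceeding_grid_rejected(self):
        with pytest.raises(ValidationError):
            simulate_phantom(
                PhantomParams(shape=(10, 10, 10),
                              ellipsoids=[((5, 5, 5), (20, 2, 2))])
            )
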