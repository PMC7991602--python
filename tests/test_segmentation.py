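"""Atlas construction, affine registration, hull extraction, fusion."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from hydroquant.phantom import build_labyrinth, simulate_sequences
from hydroquant.hydrops import preprocess_triplet
from hydroquant.pipeline import _identity_params
from hydroquant.segmentation import (
    AffineParams,
    BinaryHull,
    RegistrationConfig,
    _sample_moving,
    _world_of_indices,
    build_atlas,
    dilate_hull,
    extract_hull,
    fuse,
    register_affine,
    resample_atlas,
)
from hydroquant.volume import GridMismatchError, Volume

from conftest import make_small_spec, small_preprocess_config


@pytest.fixture(scope="module")
def reg_setup():
    spec = make_small_spec(noise_sd=0.0, seed=3)
    truth = build_labyrinth(spec)
    trip = simulate_sequences(truth, spec)
    pre = preprocess_triplet(trip.mrc, trip.ppi, trip.pei, small_preprocess_config())
    atlas = build_atlas([truth])
    return spec, truth, pre, atlas


class TestAtlas:
    def test_single_mask_occupancy_levels(self, small_truth):
        atlas = build_atlas([small_truth])
        occ = np.unique(atlas.occupancy.data)
        assert set(np.round(occ, 6)).issubset({0.0, 0.5, 1.0})
        assert atlas.side_independent

    def test_identical_masks_match_single(self, small_truth):
        one = build_atlas([small_truth])
        five = build_atlas([small_truth] * 5)
        np.testing.assert_array_equal(one.occupancy.data, five.occupancy.data)

    def test_occupancy_bounded(self, small_truth):
        atlas = build_atlas([small_truth])
        assert atlas.occupancy.data.min() >= 0.0
        assert atlas.occupancy.data.max() <= 1.0

    def test_mirror_symmetry(self, small_truth):
        atlas = build_atlas([small_truth])
        np.testing.assert_array_equal(
            atlas.occupancy.data, np.flip(atlas.occupancy.data, axis=2)
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_atlas([])


class TestRegistration:
    def test_aligned_pair_recovers_identity(self, reg_setup):
        _, _, pre, atlas = reg_setup
        p = register_affine(atlas, pre.mrc, RegistrationConfig(seed=0, shrink_factors=(2, 1)))
        assert np.abs(p.translation).max() < 0.05  # 0.1 voxel at 0.5 mm
        assert np.abs(np.asarray(p.scale) - 1).max() < 0.005

    def test_shifted_target_recovered(self, reg_setup):
        # shift the subject by +3 voxels along axis 0; in the moving->fixed
        # convention the recovered translation equals the applied shift
        _, _, pre, atlas = reg_setup
        shifted = pre.mrc.with_data(
            ndi.shift(np.asarray(pre.mrc.data, float), (3, 0, 0), order=1)
        )
        p = register_affine(atlas, shifted, RegistrationConfig(seed=0, shrink_factors=(2, 1)))
        expected = 3 * pre.mrc.voxel_size[0]
        assert abs(p.translation[0] - expected) < 0.5 * pre.mrc.voxel_size[0]
        assert np.abs(p.translation[1:]).max() < 0.5 * pre.mrc.voxel_size[0]

    def test_same_seed_identical_parameters(self, reg_setup):
        _, _, pre, atlas = reg_setup
        cfg = RegistrationConfig(seed=9, shrink_factors=(2, 1))
        p1 = register_affine(atlas, pre.mrc, cfg)
        p2 = register_affine(atlas, pre.mrc, cfg)
        np.testing.assert_array_equal(p1.to_vector(), p2.to_vector())

    def test_random_affine_recovery_within_half_voxel(self, reg_setup):
        _, _, pre, atlas = reg_setup
        rng = np.random.default_rng(7)
        center = tuple(np.asarray(pre.mrc.origin) + 0.5 * np.asarray(pre.mrc.extent_mm))
        idx = np.indices(pre.mrc.shape).reshape(3, -1).T.astype(float)
        pts_f = _world_of_indices(pre.mrc, idx)
        errs = []
        for _ in range(3):
            true_p = AffineParams(
                translation=tuple(rng.uniform(-2, 2, 3)),
                rotation=tuple(rng.uniform(-0.05, 0.05, 3)),
                scale=tuple(rng.uniform(0.95, 1.05, 3)),
                center=center,
            )
            occ = _sample_moving(atlas.occupancy, true_p.inverse_map(pts_f))
            fixed = pre.mrc.with_data(occ.reshape(pre.mrc.shape) * 255)
            est = register_affine(atlas, fixed, RegistrationConfig(seed=0, shrink_factors=(2, 1)))
            errs.append(np.abs(np.array(est.translation) - np.array(true_p.translation)).max())
        assert np.mean(errs) <= 0.5 * pre.mrc.voxel_size[0]

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AffineParams(scale=(1.0, -1.0, 1.0))


class TestHull:
    def test_noise_free_hull_matches_true_fluid_within_5pct(self, small_noise_free):
        hull = small_noise_free["hull"]
        true_fluid = int((small_noise_free["truth_proc"].label > 0).sum())
        assert abs(hull.voxel_count / true_fluid - 1) <= 0.05

    def test_noisy_hull_within_10pct(self):
        from conftest import run_small_pipeline

        out = run_small_pipeline(make_small_spec(noise_sd=10.0, seed=4), register=False)
        true_fluid = int((out["truth_proc"].label > 0).sum())
        assert abs(out["hull"].voxel_count / true_fluid - 1) <= 0.10

    def test_hull_binary_and_inside_dilated_roi(self, small_noise_free):
        hull = small_noise_free["hull"]
        mask = np.asarray(hull.mask.data)
        assert mask.dtype == bool
        assert not (mask & ~np.asarray(hull.roi.data, bool)).any()

    def test_dark_roi_is_an_error(self, small_noise_free):
        pre = small_noise_free["pre"]
        dark = pre.mrc.with_data(np.zeros(pre.mrc.shape))
        roi = pre.mrc.with_data(np.ones(pre.mrc.shape, bool))
        with pytest.raises(ValueError, match="no fluid signal"):
            extract_hull(dark, roi)

    def test_volume_mm3_consistent(self, small_noise_free):
        hull = small_noise_free["hull"]
        assert hull.volume_mm3 == pytest.approx(
            hull.voxel_count * hull.mask.voxel_volume_mm3
        )


class TestDilateAndFuse:
    def test_radius_zero_identity(self, small_noise_free):
        hull = small_noise_free["hull"]
        same = dilate_hull(hull, 0)
        np.testing.assert_array_equal(same.mask.data, hull.mask.data)

    def test_single_voxel_ball_radius_one_is_cross(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        h = BinaryHull(mask=Volume(mask, (1.0,) * 3))
        grown = dilate_hull(h, 1)
        assert grown.voxel_count == 7

    def test_dilation_monotone_in_radius(self, small_noise_free):
        hull = small_noise_free["hull"]
        d1 = dilate_hull(hull, 1)
        d2 = dilate_hull(hull, 2)
        assert not (np.asarray(hull.mask.data) & ~np.asarray(d1.mask.data)).any()
        assert not (np.asarray(d1.mask.data) & ~np.asarray(d2.mask.data)).any()

    def test_fuse_masks_outside_with_sentinel(self, small_noise_free):
        hull, pre = small_noise_free["hull"], small_noise_free["pre"]
        fused = fuse(hull, pre.mi2)
        inside = np.asarray(hull.mask.data, bool)
        assert np.isnan(fused.data[~inside]).all()
        np.testing.assert_array_equal(fused.data[inside], np.asarray(pre.mi2.data, float)[inside])

    def test_fuse_full_hull_is_identity(self, small_noise_free):
        pre = small_noise_free["pre"]
        full = BinaryHull(mask=pre.mi2.with_data(np.ones(pre.mi2.shape, bool)))
        np.testing.assert_array_equal(fuse(full, pre.mi2).data, np.asarray(pre.mi2.data, float))

    def test_fuse_empty_hull_rejected(self, small_noise_free):
        pre = small_noise_free["pre"]
        empty = BinaryHull(mask=pre.mi2.with_data(np.zeros(pre.mi2.shape, bool)))
        with pytest.raises(ValueError, match="empty"):
            fuse(empty, pre.mi2)

    def test_fuse_grid_mismatch_rejected(self, small_noise_free):
        hull = small_noise_free["hull"]
        other = Volume(np.zeros(hull.mask.shape), (0.1,) * 3)
        with pytest.raises(GridMismatchError):
            fuse(hull, other)
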