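"""Local-threshold ensemble: voting rules, aggregation, classification."""

import numpy as np
import pytest

from hydroquant.segmentation import BinaryHull
from hydroquant.volt import (
    VoltConfig,
    aggregate,
    classify_els,
    local_threshold_slicewise,
    run_volt,
    split_compartments,
)
from hydroquant.volume import Volume

from volt_oracle import brute_force_aggregation, brute_force_votes


def vol(data):
    return Volume(np.asarray(data, dtype=float), (1.0,) * 3)


def test_constant_slice_mean_offset_zero_gives_no_votes():
    v = vol(np.full((1, 16, 16), 50.0))
    out = local_threshold_slicewise(v, 0, "mean", 3)
    assert not out.data.any()


def test_dark_patch_votes_exactly():
    # bright 16x16 field with a 3x3 dark patch: all 9 patch voxels vote,
    # nothing else does (verified against the brute-force window means)
    field = np.full((1, 16, 16), 200.0)
    field[0, 6:9, 6:9] = 40.0
    v = vol(field)
    out = local_threshold_slicewise(v, 0, "mean", 6, offset=0.0)
    expected = brute_force_votes(field, 0, "mean", 6, offset=0.0)
    np.testing.assert_array_equal(out.data, expected)
    assert out.data[0, 6:9, 6:9].all()
    assert out.data.sum() == 9


def test_niblack_k0_equals_mean_offset0():
    rng = np.random.default_rng(0)
    v = vol(rng.uniform(0, 255, (4, 12, 12)))
    nib = local_threshold_slicewise(v, 1, "niblack", 3, k=0.0)
    mean = local_threshold_slicewise(v, 1, "mean", 3, offset=0.0)
    np.testing.assert_array_equal(nib.data, mean.data)


def test_radius_beyond_slice_extent_rejected():
    v = vol(np.zeros((4, 8, 8)))
    with pytest.raises(ValueError, match="radius"):
        local_threshold_slicewise(v, 0, "mean", 20)


def test_oracle_equivalence_on_random_masked_volumes():
    cfg = VoltConfig(window_radii=(2, 4))
    rng = np.random.default_rng(42)
    for _ in range(3):
        data = rng.uniform(0, 255, (10, 12, 8))
        data[rng.random(data.shape) < 0.2] = np.nan  # sentinel voxels
        v = vol(data)
        members = [
            local_threshold_slicewise(v, ax, algo, r, k=cfg.niblack_k, offset=cfg.mean_offset)
            for ax, algo, r in cfg.provenance()
        ]
        agg = aggregate(members, cfg.provenance())
        np.testing.assert_array_equal(
            agg.votes.data, brute_force_aggregation(data, cfg)
        )


class TestAggregate:
    def test_zeros_and_ones(self):
        zero = vol(np.zeros((3, 3, 3)))
        zeros = [zero.with_data(np.zeros((3, 3, 3), bool))] * 12
        ones = [zero.with_data(np.ones((3, 3, 3), bool))] * 12
        assert not aggregate(zeros).votes.data.any()
        assert (aggregate(ones).votes.data == 12).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        base = vol(np.zeros((4, 4, 4)))
        members = [base.with_data(rng.random((4, 4, 4)) < 0.5) for _ in range(12)]
        a = aggregate(members).votes.data
        b = aggregate(members[::-1]).votes.data
        np.testing.assert_array_equal(a, b)

    def test_wrong_count_rejected(self):
        base = vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="expected"):
            aggregate([base] * 3, provenance=[None] * 12)


class TestClassify:
    def _agg(self, votes):
        v = vol(np.asarray(votes, dtype=float))
        from hydroquant.volt import AggregationVolume

        return AggregationVolume(votes=v.with_data(np.asarray(votes)), provenance=[None] * 12)

    def test_cutoff_one_on_full_votes_equals_hull(self):
        votes = np.full((3, 3, 3), 12, dtype=np.uint8)
        hull_mask = np.zeros((3, 3, 3), bool)
        hull_mask[1] = True
        hull = BinaryHull(mask=Volume(hull_mask, (1.0,) * 3))
        els = classify_els(self._agg(votes), VoltConfig(vote_cutoff=1), hull)
        np.testing.assert_array_equal(els.mask.data, hull_mask)

    def test_strict_cutoff_excludes_eleven_votes_at_twelve(self):
        votes = np.zeros((3, 3, 3), dtype=np.uint8)
        votes[0, 0, 0] = 11
        hull = BinaryHull(mask=Volume(np.ones((3, 3, 3), bool), (1.0,) * 3))
        els = classify_els(self._agg(votes), VoltConfig(vote_cutoff=12), hull)
        assert not els.mask.data.any()

    def test_lowering_cutoff_never_shrinks_mask(self, small_noise_free):
        agg, hull = small_noise_free["agg"], small_noise_free["hull"]
        prev = None
        for cutoff in (12, 11, 8, 4, 1):
            mask = classify_els(
                agg, VoltConfig(window_radii=(3, 5), vote_cutoff=cutoff), hull
            ).mask.data
            if prev is not None:
                assert not (prev & ~mask).any()
            prev = mask


def test_orientation_consistency_under_rotation():
    # rotating the volume 90 degrees about axis 0 permutes the slice
    # orientations; with shared radii the vote map rotates along
    cfg = VoltConfig(window_radii=(2, 3))
    rng = np.random.default_rng(5)
    data = rng.uniform(0, 255, (6, 10, 10))
    hull = BinaryHull(mask=Volume(np.ones(data.shape, bool), (1.0,) * 3))
    agg, _ = run_volt(vol(data), cfg, hull)
    rot = np.rot90(data, axes=(1, 2)).copy()
    hull_r = BinaryHull(mask=Volume(np.ones(rot.shape, bool), (1.0,) * 3))
    agg_r, _ = run_volt(vol(rot), cfg, hull_r)
    np.testing.assert_array_equal(
        np.rot90(agg_r.votes.data, axes=(2, 1)), agg.votes.data
    )


class TestSplit:
    def test_compartment_partition_sums_to_whole(self, small_noise_free):
        els = small_noise_free["els"]
        total = int(np.count_nonzero(els.mask.data))
        c = int(np.count_nonzero(els.cochlear.data))
        v = int(np.count_nonzero(els.vestibular.data))
        assert c + v <= total
        comp = small_noise_free["truth_proc"].compartment
        in_compartments = int(np.count_nonzero(np.asarray(els.mask.data) & (comp > 0)))
        assert c + v == in_compartments

    def test_vestibular_mask_disjoint_from_true_cochlea(self, small_noise_free):
        els = small_noise_free["els"]
        comp = small_noise_free["truth_proc"].compartment
        assert not (np.asarray(els.vestibular.data) & (comp == 1)).any()

    def test_empty_cochlear_box(self, small_noise_free):
        els = small_noise_free["els"]
        shape = els.mask.shape
        out = split_compartments(
            els,
            boxes={
                "cochlea": (slice(0, 0), slice(0, 0), slice(0, 0)),
                "vestibule": (slice(0, shape[0]), slice(0, shape[1]), slice(0, shape[2])),
            },
        )
        assert not out.cochlear.data.any()
        np.testing.assert_array_equal(out.vestibular.data, els.mask.data)

    def test_overlapping_boxes_rejected(self, small_noise_free):
        els = small_noise_free["els"]
        box = (slice(0, 2), slice(0, 2), slice(0, 2))
        with pytest.raises(ValueError, match="overlap"):
            split_compartments(els, boxes={"cochlea": box, "vestibule": box})
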