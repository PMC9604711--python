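import json

import numpy as np
import pytest
from scipy import ndimage

from lscf.cf import connectivity_scores, threshold_scores
from lscf.lscf import lscf_segment
from lscf.synthetic import (
    COMPASS,
    Fixture,
    GapSpec,
    VesselTreeSpec,
    add_salt_noise,
    build_fixture,
    generate_vessel_tree,
    punch_gaps,
    save_fixture,
    two_segment_fixture,
)

EIGHT = np.ones((3, 3), bool)


def n_components(mask):
    return ndimage.label(mask, structure=EIGHT)[1]


class TestGenerateVesselTree:
    def test_deterministic_per_seed(self):
        spec = VesselTreeSpec(seed=7)
        np.testing.assert_array_equal(generate_vessel_tree(spec), generate_vessel_tree(spec))
        assert generate_vessel_tree(spec).any()

    def test_different_seeds_differ(self):
        a = generate_vessel_tree(VesselTreeSpec(seed=1))
        b = generate_vessel_tree(VesselTreeSpec(seed=2))
        assert (a != b).any()

    def test_straight_single_branch(self):
        spec = VesselTreeSpec(
            image_size=(64, 64),
            n_branches=1,
            branch_length_range=(20, 20),
            width_range=(1, 1),
            turn_prob=0.0,
            seed=3,
        )
        m = generate_vessel_tree(spec)
        s = connectivity_scores(m)
        assert m.sum() == 20
        assert (s[m] == 20).all()
        assert n_components(m) == 1

    def test_width_three_cross_sections(self):
        spec = VesselTreeSpec(
            image_size=(64, 64),
            n_branches=1,
            branch_length_range=(20, 20),
            width_range=(3, 3),
            turn_prob=0.0,
            seed=5,
        )
        m = generate_vessel_tree(spec)
        # every foreground pixel's 3x3 block holds a full-width stamp nearby:
        # the distance transform along the centerline must reach >= 1.5
        dist = ndimage.distance_transform_edt(m)
        assert dist.max() >= 1.5
        assert m.sum() >= 3 * 20 * 0.8  # about 3 pixels of width per step

    def test_tree_is_single_component(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=11))
        assert n_components(m) == 1


class TestPunchGaps:
    def test_no_gaps_identity(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=4))
        fx = punch_gaps(m, GapSpec(n_gaps=0, seed=0))
        np.testing.assert_array_equal(fx.observed, fx.truth)

    def test_deterministic_per_seed(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=4))
        a = punch_gaps(m, GapSpec(seed=9))
        b = punch_gaps(m, GapSpec(seed=9))
        np.testing.assert_array_equal(a.observed, b.observed)
        assert [g for _, g in a.gaps] == [g for _, g in b.gaps]

    def test_straight_segment_gap_splits_component(self):
        spec = VesselTreeSpec(
            image_size=(64, 64),
            n_branches=1,
            branch_length_range=(20, 20),
            width_range=(1, 1),
            turn_prob=0.0,
            seed=3,
        )
        m = generate_vessel_tree(spec)
        fx = punch_gaps(m, GapSpec(n_gaps=1, gap_length_range=(2, 2), seed=1))
        removed = sum(len(px) for px, _ in fx.gaps)
        assert fx.observed.sum() == 20 - removed
        assert n_components(fx.observed) == 2

    def test_gaps_disconnect(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=8))
        fx = punch_gaps(m, GapSpec(n_gaps=6, seed=2))
        assert n_components(fx.observed) > n_components(fx.truth)
        assert sum(len(px) for px, _ in fx.gaps) > 0
        # observed = truth minus exactly the recorded pixels
        diff = fx.truth & ~fx.observed
        recorded = np.zeros_like(m)
        for px, _ in fx.gaps:
            for p in px:
                recorded[p.row, p.col] = True
        np.testing.assert_array_equal(diff, recorded)

    def test_too_many_gaps_rejected(self):
        m = np.zeros((20, 20), bool)
        m[10, 5:15] = True
        with pytest.raises(ValueError, match="host"):
            punch_gaps(m, GapSpec(n_gaps=10, seed=0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            punch_gaps(np.zeros((8, 8), bool), GapSpec(n_gaps=1, seed=0))


class TestAddSaltNoise:
    def test_zero_density_unchanged(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=4))
        np.testing.assert_array_equal(add_salt_noise(m, 0.0, seed=1), m)

    def test_deterministic_per_seed(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=4))
        np.testing.assert_array_equal(
            add_salt_noise(m, 0.002, seed=5), add_salt_noise(m, 0.002, seed=5)
        )

    def test_added_pixels_are_isolated_and_removed_by_cf(self):
        m = generate_vessel_tree(VesselTreeSpec(seed=4))
        noisy = add_salt_noise(m, 0.003, seed=5)
        added = noisy & ~m
        assert added.sum() > 0
        scores = connectivity_scores(noisy)
        assert (scores[added] == 1).all()
        cleaned = threshold_scores(scores, 1)
        assert not (cleaned & added).any()


class TestBuildFixture:
    def test_observed_is_truth_minus_gaps_plus_noise(self):
        fx = build_fixture(VesselTreeSpec(seed=6), GapSpec(seed=7), noise_seed=8)
        gap_mask = np.zeros_like(fx.truth)
        for px, _ in fx.gaps:
            for p in px:
                gap_mask[p.row, p.col] = True
        noise_mask = np.zeros_like(fx.truth)
        for p in fx.noise_pixels:
            noise_mask[p.row, p.col] = True
        np.testing.assert_array_equal(fx.observed, (fx.truth & ~gap_mask) | noise_mask)

    def test_end_to_end_recovery_and_accuracy_gain_without_noise(self):
        # every punched gap is short enough for the default budgets, so the
        # bridged output restores the truth's component count and beats the
        # plain connectivity filter on accuracy
        from lscf.evaluation import confusion_counts, metrics

        for seed in (21, 22, 23):
            fx = build_fixture(
                VesselTreeSpec(seed=seed), GapSpec(seed=seed + 100), noise_density=0.0
            )
            seg = lscf_segment(fx.observed)
            assert n_components(seg) == n_components(fx.truth)
            acc_ls = metrics(confusion_counts(seg, fx.truth)).accuracy
            cf_seg = threshold_scores(connectivity_scores(fx.observed), 1)
            acc_cf = metrics(confusion_counts(cf_seg, fx.truth)).accuracy
            assert acc_ls > acc_cf

    def test_noise_pixels_absent_from_all_pipelines(self):
        from lscf.morphology import cf_plus_closing

        fx = build_fixture(VesselTreeSpec(seed=6), GapSpec(seed=7), noise_seed=8)
        isolated = [
            p
            for p in fx.noise_pixels
            # only noise out of bridging reach is guaranteed deleted by LS-CF
            if not fx.truth[
                max(0, p.row - 6) : p.row + 7, max(0, p.col - 6) : p.col + 7
            ].any()
        ]
        cf_out = threshold_scores(connectivity_scores(fx.observed), 1)
        cc_out = cf_plus_closing(fx.observed)
        ls_out = lscf_segment(fx.observed)
        for p in fx.noise_pixels:
            assert not cf_out[p.row, p.col]
            assert not cc_out[p.row, p.col]
        for p in isolated:
            assert not ls_out[p.row, p.col]


class TestTwoSegmentFixture:
    def test_geometry(self):
        fx = two_segment_fixture((0, 1), gap_len=2, seg_len=5)
        assert fx.truth.sum() == 12
        assert fx.observed.sum() == 10
        assert len(fx.gaps[0][0]) == 2

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            two_segment_fixture((0, 2), gap_len=2)


class TestSaveFixture:
    def test_export_roundtrip(self, tmp_path):
        import imageio.v3 as iio

        fx = build_fixture(VesselTreeSpec(seed=6), GapSpec(seed=7), noise_seed=8)
        save_fixture(fx, tmp_path)
        obs = iio.imread(tmp_path / "observed.png") > 0
        np.testing.assert_array_equal(obs, fx.observed)
        sidecar = json.loads((tmp_path / "fixture.json").read_text())
        assert len(sidecar["gaps"]) == len(fx.gaps)
        assert len(sidecar["noise_pixels"]) == len(fx.noise_pixels)
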