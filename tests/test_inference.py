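"""Permutation nulls, FDR, difference tests, searchlight, TFCE, max-stat FWE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from liminal import inference, synth


class TestPermuteLabels:
    def test_per_run_histograms_preserved(self, rng):
        labels = np.array(list("aabbccdd" * 3))
        runs = np.repeat([0, 1, 2], 8)
        perm = inference.permute_labels_within_run(labels, runs, rng)
        for r in range(3):
            assert sorted(labels[runs == r]) == sorted(perm[runs == r])

    def test_single_trial_run_unchanged(self, rng):
        labels = np.array(["a", "b", "c"])
        runs = np.array([0, 1, 2])
        perm = inference.permute_labels_within_run(labels, runs, rng)
        assert np.array_equal(perm, labels)

    def test_fixed_seed_reproducible(self):
        labels = np.array(list("abcd" * 4))
        runs = np.repeat([0, 1], 8)
        a = inference.permute_labels_within_run(labels, runs, np.random.default_rng(3))
        b = inference.permute_labels_within_run(labels, runs, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestGroupNull:
    def test_group_null_size_and_mean(self, rng):
        subject_data = [
            synth.make_null_roi_data(30, 4, 2, rng) for _ in range(4)
        ]
        null = inference.build_group_null(
            subject_data, n_subject_perms=20, n_group=1000, rng=rng
        )
        assert null.group_null.shape == (1000,)
        assert null.subject_perms.shape == (4, 20)
        se = null.group_null.std() / np.sqrt(1000) + 0.03
        assert abs(null.group_null.mean() - 0.25) < 3 * se

    def test_degenerate_single_subject_single_sample(self, rng):
        subject_data = [synth.make_null_roi_data(10, 3, 2, rng)]
        null = inference.build_group_null(
            subject_data, n_subject_perms=1, n_group=1, rng=rng
        )
        assert null.group_null[0] == null.subject_perms[0, 0]


class TestPermutationPvalue:
    def test_observed_above_all_nulls(self):
        assert inference.permutation_pvalue(1.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_observed_below_all_nulls(self):
        assert inference.permutation_pvalue(-1.0, np.zeros(1000)) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            inference.permutation_pvalue(0.5, np.array([]))


class TestFdr:
    def test_step_up_thresholds_hand_computed(self):
        # k q / m for m = 4, q = 0.05: thresholds .0125, .025, .0375, .05;
        # p = (.01, .02, .03, .2): largest k with p_(k) <= k q / m is 3
        flags = inference.fdr_bh(np.array([0.01, 0.02, 0.03, 0.2]), q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_above_q_none_significant(self):
        assert not inference.fdr_bh(np.array([0.2, 0.5, 0.9]), q=0.05).any()

    def test_single_small_p_significant(self):
        assert inference.fdr_bh(np.array([0.01]), q=0.05).all()


class TestAccuracyDifference:
    def test_identical_accuracies_give_large_p(self, rng):
        obs = np.array([0.3, 0.32, 0.28])
        perms = rng.uniform(0.2, 0.3, (3, 30))
        a = inference.PermutationNull(obs, perms, np.array([]))
        b = inference.PermutationNull(obs.copy(), perms.copy(), np.array([]))
        diff, p = inference.accuracy_difference_test(a, b, n_group=500, rng=rng)
        assert diff == 0.0
        assert p > 0.3

    def test_subject_mismatch_rejected(self, rng):
        a = inference.PermutationNull(np.zeros(3), np.zeros((3, 5)), np.array([]))
        b = inference.PermutationNull(np.zeros(4), np.zeros((4, 5)), np.array([]))
        with pytest.raises(ValueError):
            inference.accuracy_difference_test(a, b, rng=rng)


class TestSearchlight:
    def test_interior_sphere_has_123_voxels(self):
        assert len(inference.sphere_offsets(3)) == 123

    def test_no_signal_map_near_chance(self, rng):
        X, y, runs = synth.make_null_volume_data((8, 8, 8), 4, 2, rng)
        mask = np.ones((8, 8, 8), bool)
        m = inference.searchlight_map(X, y, runs, mask, decoder="nearest_centroid")
        assert abs(np.nanmean(m) - 0.25) < 0.05

    def test_edge_spheres_truncated_to_mask(self, rng):
        X, y, runs = synth.make_null_volume_data((6, 6, 6), 3, 2, rng)
        mask = np.zeros((6, 6, 6), bool)
        mask[:3] = True  # half the grid: edge spheres must not see the rest
        m = inference.searchlight_map(X, y, runs, mask, decoder="nearest_centroid")
        assert np.isnan(m[3:]).all()
        assert np.isfinite(m[:3]).all()

    def test_svm_and_centroid_paths_agree_on_strong_signal(self, rng):
        dims = (5, 5, 5)
        labels = np.tile(np.array(synth.CATEGORIES), 6)
        runs = np.repeat(np.arange(3), 8)
        centers = {c: rng.normal(0, 1, dims) * 4 for c in synth.CATEGORIES}
        X = np.stack([centers[c] + rng.normal(0, 0.3, dims) for c in labels])
        mask = np.ones(dims, bool)
        m_svm = inference.searchlight_map(X, labels, runs, mask, radius=2, decoder="svm")
        m_nc = inference.searchlight_map(
            X, labels, runs, mask, radius=2, decoder="nearest_centroid"
        )
        assert np.nanmean(m_svm) > 0.9
        assert np.nanmean(m_nc) > 0.9


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert not inference.tfce_transform(np.zeros((4, 4, 4))).any()

    def test_single_voxel_closed_form(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 1.7
        out = inference.tfce_transform(v, n_steps=4000)
        assert out[2, 2, 2] == pytest.approx(1.7**3 / 3, rel=2e-3)

    @given(st.integers(min_value=0, max_value=26), st.floats(0.1, 2.0))
    def test_raising_a_voxel_never_decreases_output(self, flat_idx, bump):
        rng = np.random.default_rng(42)
        v = rng.uniform(0, 1, (3, 3, 3))
        dh = 0.05  # fixed integration step so outputs are comparable
        base = inference.tfce_transform(v, dh=dh)
        v2 = v.copy()
        v2.ravel()[flat_idx] += bump
        raised = inference.tfce_transform(v2, dh=dh)
        assert (raised >= base - 1e-12).all()

    def test_six_connectivity_separates_diagonal_voxels(self):
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = v[1, 1, 1] = 1.0  # diagonal neighbours: two clusters
        out = inference.tfce_transform(v, n_steps=50)
        single = np.zeros((3, 3, 3))
        single[0, 0, 0] = 1.0
        out_single = inference.tfce_transform(single, n_steps=50)
        assert out[0, 0, 0] == pytest.approx(out_single[0, 0, 0])


class TestMaxStat:
    def test_null_length_and_extreme_voxel_p(self, rng):
        perm_maps = rng.uniform(0, 1, (50, 4, 4, 4))
        true_map = np.zeros((4, 4, 4))
        true_map[0, 0, 0] = 5.0  # above every null maximum
        p, sig, maxima = inference.maxstat_fwe(true_map, perm_maps)
        assert len(maxima) == 50
        assert p[0, 0, 0] == pytest.approx(1 / 51)
        assert sig[0, 0, 0]
        assert not sig[1:].any()
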