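"""Synthetic sessions, behavior, ROI geometry, beta patterns, BOLD forward model."""

import numpy as np
import pandas as pd
import pytest

from liminal import decoding, glm, synth


class TestSession:
    def test_default_session_counts(self, rng):
        table = synth.make_session(15, rng)
        assert len(table) == 360
        per_run = table.groupby("run").size()
        assert (per_run == 24).all()
        scr = table.groupby("run")["image_type"].apply(lambda s: (s == "scrambled").sum())
        assert (scr == 4).all()

    def test_one_trial_per_stimulus_per_run(self, rng):
        table = synth.make_session(3, rng)
        counts = table.groupby(["run", "stimulus_id"]).size()
        assert (counts == 1).all()

    def test_timing_invariants(self, rng):
        table = synth.make_session(4, rng)
        for _, run in table.groupby("run"):
            onsets = run["onset_s"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            prev_end = np.concatenate(
                [[0.0], onsets[:-1] + synth.STIM_DURATION_S
                 + run["post_fixation_s"].to_numpy()[:-1] + synth.QUESTION_DURATION_S]
            )
            pre_fix = onsets - prev_end
            assert np.all(pre_fix >= 6.0 - 1e-9)
            assert np.all(pre_fix <= 20.0 + 1e-9)
        assert set(table["post_fixation_s"]) <= {4.0, 6.0}


class TestBehavior:
    def test_zero_recognition_probability(self, rng):
        truth = synth.GroundTruth(behavior=synth.Behavior(p_recognize_real=0.0))
        table = synth.simulate_behavior(synth.make_session(2, rng), truth, rng)
        real = table[table["image_type"] == "real"]
        assert (real["recognition"] == "no").all()

    def test_chance_accuracy_when_unrecognized_guessing(self, rng):
        truth = synth.GroundTruth(
            behavior=synth.Behavior(p_recognize_real=0.0, acc_unrecognized=0.25)
        )
        table = synth.simulate_behavior(synth.make_session(40, rng), truth, rng)
        real = table[table["image_type"] == "real"]
        acc = (real["reported_category"] == real["category"]).mean()
        se = np.sqrt(0.25 * 0.75 / len(real))
        assert abs(acc - 0.25) < 3 * se

    def test_recognition_rate_matches_parameter(self, rng):
        truth = synth.GroundTruth()
        table = synth.simulate_behavior(synth.make_session(25, rng), truth, rng)
        real = table[table["image_type"] == "real"]
        rate = (real["recognition"] == "yes").mean()
        se = np.sqrt(0.5 * 0.5 / len(real))
        assert abs(rate - 0.50) < 3 * se


class TestRoiGeometry:
    def test_disjoint_masks_with_exact_counts(self):
        atlas = synth.make_roi_geometry(
            (30, 30, 30),
            [synth.RoiSpec("a", "cortical_activated", 100),
             synth.RoiSpec("b", "subcortical", 100)],
        )
        assert int(atlas.masks["a"].sum()) == 100
        assert int(atlas.masks["b"].sum()) == 100
        assert not (atlas.masks["a"] & atlas.masks["b"]).any()

    def test_masks_are_connected(self, small_atlas):
        from scipy import ndimage

        for mask in small_atlas.masks.values():
            _, n = ndimage.label(mask)
            assert n == 1

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            synth.make_roi_geometry((4, 4, 4), [synth.RoiSpec("big", "subcortical", 500)])

    def test_overlap_error_with_explicit_origins(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.make_roi_geometry(
                (20, 20, 20),
                [synth.RoiSpec("a", "subcortical", 64, origin=(0, 0, 0)),
                 synth.RoiSpec("b", "subcortical", 64, origin=(1, 1, 1))],
            )

    def test_default_atlas_class_counts(self):
        atlas = synth.default_atlas()
        classes = list(atlas.classes.values())
        assert classes.count("cortical_activated") == 10
        assert classes.count("cortical_deactivated") == 6
        assert classes.count("subcortical") == 4


class TestBetaDataset:
    def test_amplitude_directions(self, small_atlas, small_dataset):
        ds = small_dataset
        for roi, expected_sign in (("vis", 1.0), ("dmn", -1.0)):
            cols = ds.roi_columns(roi)
            rec, _, _ = ds.select("yes", "real")
            unrec, _, _ = ds.select("no", "real")
            m_rec, m_unrec = rec[:, cols].mean(), unrec[:, cols].mean()
            assert np.sign(m_rec) == expected_sign
            assert abs(m_rec) > abs(m_unrec)

    def test_no_signal_decodes_at_chance(self, small_atlas, rng):
        truth = synth.GroundTruth().with_no_signal()
        table = synth.simulate_behavior(synth.make_session(6, rng), truth, rng)
        ds = synth.make_beta_dataset(table, small_atlas, truth, rng)
        X, y, runs = ds.select("yes", "real")
        res = decoding.cross_validate(X[:, ds.roi_columns("vis")], y, runs)
        assert abs(res.balanced_accuracy - 0.25) < 0.22  # loose: single draw

    def test_noiseless_strong_signal_decodes_perfectly(self, small_atlas, rng):
        truth = synth.GroundTruth(noise_sd=0.0, between_subject_sd=0.0)
        table = synth.simulate_behavior(synth.make_session(4, rng), truth, rng)
        ds = synth.make_beta_dataset(table, small_atlas, truth, rng)
        X, y, runs = ds.select("yes", "real")
        res = decoding.cross_validate(X[:, ds.roi_columns("vis")], y, runs)
        assert res.balanced_accuracy == 1.0

    def test_determinism_under_master_seed(self, small_atlas):
        truth = synth.GroundTruth()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            table = synth.simulate_behavior(synth.make_session(2, rng), truth, rng)
            out.append(synth.make_beta_dataset(table, small_atlas, truth, rng))
        assert np.array_equal(out[0].X, out[1].X)
        assert out[0].samples.equals(out[1].samples)


class TestBoldForwardModel:
    def test_noiseless_recovery_and_hrf_peak(self, rng):
        truth = synth.GroundTruth()
        table = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        run = table[table["run"] == 0]
        design = glm.build_design(run)
        n_reg = design.matrix.shape[1]
        betas = np.zeros((n_reg, 3))
        betas[: len(design.stimulus_names)] = rng.normal(0, 1, (len(design.stimulus_names), 3))
        bold = synth.make_bold_run(run, betas, rng, noise_sd=0.0)
        fit = glm.fit_glm(bold.data, bold.design)
        assert np.abs(fit.betas - bold.true_betas).max() < 1e-8

    def test_single_event_peaks_near_hrf_mode(self):
        table = pd.DataFrame(
            {"subject": [0], "run": [0], "trial_index": [0], "onset_s": [0.0],
             "stimulus_id": ["face_0"], "category": ["face"], "image_type": ["real"],
             "recognition": ["yes"], "reported_category": ["face"],
             "post_fixation_s": [4.0]}
        )
        design = glm.build_design(table, n_vols=20)
        reg = design.column("face_yes_real")
        # gamma mode at (shape-1)*scale = 4.5 s -> nearest TR sample at 4 s
        assert np.argmax(reg) * design.tr == pytest.approx(4.0)

    def test_white_noise_residuals_uncorrelated(self, rng):
        from statsmodels.stats.diagnostic import acorr_ljungbox

        truth = synth.GroundTruth()
        table = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        run = table[table["run"] == 0]
        design = glm.build_design(run)
        betas = np.zeros((design.matrix.shape[1], 1))
        bold = synth.make_bold_run(run, betas, rng, noise_sd=1.0, ar_coef=0.0)
        fit = glm.fit_glm(bold.data, bold.design)
        resid = bold.data - bold.design.matrix @ fit.betas
        lb = acorr_ljungbox(resid[:, 0], lags=[10])
        assert lb["lb_pvalue"].iloc[0] > 0.05
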