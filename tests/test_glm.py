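"""Gamma HRF, design construction, OLS fitting, PSC, sign-flip group test."""

import numpy as np
import pytest

from liminal import glm, synth


class TestGammaHrf:
    def test_moment_matched_shape_and_scale(self):
        # mean 6 s, sd 3 s -> shape 4, scale 1.5; mode (shape-1)*scale = 4.5 s
        h = glm.gamma_hrf()
        assert h.peak_time == pytest.approx(4.5, abs=h.dt)

    def test_nonnegative_peak_normalized(self):
        h = glm.gamma_hrf()
        assert h.values.min() >= 0.0
        assert h.values.max() == pytest.approx(1.0)
        assert len(h.values) * h.dt <= 32.0 + 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            glm.gamma_hrf(lag=-1.0)


class TestDesign:
    @pytest.fixture()
    def run_table(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        return t[t["run"] == 0]

    def test_regressors_match_present_conditions(self, run_table):
        design = glm.build_design(run_table)
        present = (
            run_table[run_table["recognition"].isin(["yes", "no"])]
            .groupby(["category", "recognition", "image_type"])
            .size()
        )
        assert len(design.stimulus_names) == len(present)
        assert len(design.stimulus_names) <= 16
        assert "questions" in design.names
        assert len(set(design.names)) == len(design.names)

    def test_absent_condition_omitted(self, run_table):
        reduced = run_table[run_table["category"] != "face"]
        design = glm.build_design(reduced)
        assert not any(n.startswith("face") for n in design.stimulus_names)

    def test_onset_beyond_run_rejected(self, run_table):
        with pytest.raises(ValueError, match="beyond"):
            glm.build_design(run_table, n_vols=5)

    def test_convolution_linearity(self, run_table):
        """Two events produce the sum of the single-event regressors."""
        one = run_table.iloc[[0]].assign(onset_s=[10.0])
        two = run_table.iloc[[1]].assign(
            onset_s=[60.0],
            category=one["category"].iloc[0],
            recognition=one["recognition"].iloc[0],
            image_type=one["image_type"].iloc[0],
        )
        import pandas as pd

        both = pd.concat([one, two])
        name = f"{one['category'].iloc[0]}_{one['recognition'].iloc[0]}_{one['image_type'].iloc[0]}"
        r1 = glm.build_design(one, n_vols=60).column(name)
        r2 = glm.build_design(two, n_vols=60).column(name)
        r12 = glm.build_design(both, n_vols=60).column(name)
        assert np.allclose(r12, r1 + r2, atol=1e-12)


class TestBidsEvents:
    def test_events_table_builds_same_design(self, rng):
        import pandas as pd

        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        run = t[t["run"] == 0]
        events = pd.DataFrame(
            {
                "onset": run["onset_s"].to_numpy(),
                "duration": 8 / 120.0,
                "trial_type": run["category"] + "_" + run["recognition"] + "_" + run["image_type"],
                "post_fixation_s": run["post_fixation_s"].to_numpy(),
            }
        )
        from_events = glm.build_design(glm.run_table_from_events(events))
        direct = glm.build_design(run)
        assert from_events.names == direct.names
        assert np.allclose(from_events.matrix, direct.matrix)

    def test_malformed_trial_type_rejected(self):
        import pandas as pd

        events = pd.DataFrame({"onset": [1.0], "duration": [0.1], "trial_type": ["face"]})
        with pytest.raises(ValueError, match="trial_type"):
            glm.run_table_from_events(events)


class TestFit:
    def test_pure_noise_betas_near_zero(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        design = glm.build_design(t[t["run"] == 0])
        Y = rng.normal(0, 1, (design.matrix.shape[0], 200))
        fit = glm.fit_glm(Y, design)
        stim = fit.betas[: len(design.stimulus_names)]
        assert abs(stim.mean()) < 0.1

    def test_residuals_orthogonal_to_design(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        design = glm.build_design(t[t["run"] == 0])
        Y = rng.normal(0, 1, (design.matrix.shape[0], 5))
        fit = glm.fit_glm(Y, design)
        resid = Y - design.matrix @ fit.betas
        assert np.abs(design.matrix.T @ resid).max() < 1e-8

    def test_duplicated_regressor_raises_naming_column(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        design = glm.build_design(t[t["run"] == 0])
        design.matrix = np.column_stack([design.matrix, design.matrix[:, 0]])
        design.names = design.names + [design.names[0] + "_dup"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            glm.fit_glm(np.zeros((design.matrix.shape[0], 1)), design)


class TestPsc:
    def test_linearity_and_zero(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        design = glm.build_design(t[t["run"] == 0])
        n_reg = design.matrix.shape[1]
        betas = np.zeros((n_reg, 2))
        name = design.stimulus_names[0]
        betas[design.names.index(name)] = [1.0, 2.0]
        fit = glm.GlmFit(betas, np.zeros(2), design)
        psc = glm.percent_signal_change(fit, np.array([100.0, 100.0]))
        assert psc.loc[name, 1] == pytest.approx(2 * psc.loc[name, 0])
        zero_fit = glm.GlmFit(np.zeros_like(betas), np.zeros(2), design)
        assert np.allclose(glm.percent_signal_change(zero_fit, np.array([100.0, 100.0])), 0.0)

    def test_generator_roundtrip_recovers_planted_psc(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        run = t[t["run"] == 0]
        design = glm.build_design(run)
        betas = np.zeros((design.matrix.shape[1], 20))
        # plant a +0.2 PSC response in every stimulus condition:
        # beta = psc/100 * baseline / regressor height
        planted = 0.2
        height = glm.regressor_peak_height()
        for name in design.stimulus_names:
            betas[design.names.index(name)] = planted / 100.0 * 100.0 / height
        bold = synth.make_bold_run(run, betas, rng, noise_sd=0.3, baseline=100.0)
        fit = glm.fit_glm(bold.data, bold.design)
        psc = glm.percent_signal_change(fit, bold.data.mean(axis=0))
        assert np.asarray(psc).mean() == pytest.approx(planted, rel=0.10)

    def test_zero_mean_voxel_rejected(self, rng):
        truth = synth.GroundTruth()
        t = synth.simulate_behavior(synth.make_session(1, rng), truth, rng)
        design = glm.build_design(t[t["run"] == 0])
        fit = glm.GlmFit(np.zeros((design.matrix.shape[1], 1)), np.zeros(1), design)
        with pytest.raises(ValueError):
            glm.percent_signal_change(fit, np.array([0.0]))


class TestGroupContrast:
    def test_identical_positive_effects_reach_minimum_p(self, rng):
        effects = np.full((20, 3), 0.5)
        res = glm.group_contrast(effects, n_flips=1000, rng=rng)
        assert np.allclose(res.p, 1.0 / 1001.0)

    def test_symmetric_null_calibration(self, rng):
        effects = rng.normal(0.0, 1.0, (12, 400))
        res = glm.group_contrast(effects, n_flips=200, rng=rng)
        rate = (res.p <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 400)
        assert rate <= 0.05 + 3 * se

    def test_generator_contrast_signs(self, small_atlas, small_dataset):
        ds = small_dataset
        rec, _, _ = ds.select("yes", "real")
        unrec, _, _ = ds.select("no", "real")
        diff_act = rec[:, ds.roi_columns("vis")].mean() - unrec[:, ds.roi_columns("vis")].mean()
        diff_deact = rec[:, ds.roi_columns("dmn")].mean() - unrec[:, ds.roi_columns("dmn")].mean()
        assert diff_act > 0 > diff_deact
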