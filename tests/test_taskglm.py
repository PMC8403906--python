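"""FIR design assembly, GLM estimation and deactivation contrasts."""

import numpy as np
import pandas as pd
import pytest

import hippoparc as hp
from hippoparc.data import BoldMatrix
from hippoparc.synthetic import TaskSpec, make_task_run
from hippoparc.taskglm import (
    build_fir_design,
    deactivation_contrast,
    fit_glm,
    region_deactivation_compare,
)


def events_df(onsets, condition="task"):
    return pd.DataFrame({"condition": condition, "onset_frame": onsets})


class TestFirDesign:
    def test_single_event_one_hot_columns(self):
        d = build_fir_design(events_df([0]), n_frames=20, n_lags=8,
                             include_intercept=False)
        assert d.matrix.shape == (20, 8)
        for k in range(8):
            expected = np.zeros(20)
            expected[k] = 1.0
            assert np.array_equal(d.matrix[:, k], expected)

    def test_two_events_column_sums(self):
        d = build_fir_design(events_df([0, 10]), n_frames=30, n_lags=8,
                             include_intercept=False)
        assert np.allclose(d.matrix.sum(axis=0), 2.0)

    def test_overlapping_events_sum_indicators(self):
        d = build_fir_design(events_df([0, 2]), n_frames=20, n_lags=8,
                             include_intercept=False)
        # frame 2 carries lag3 of the first event and lag1 of the second
        assert d.matrix[2, d.names.index("task:lag3")] == 1.0
        assert d.matrix[2, d.names.index("task:lag1")] == 1.0

    def test_rank_deficiency_names_columns(self):
        ev = pd.DataFrame({"condition": ["a", "b"], "onset_frame": [0, 0]})
        with pytest.raises(ValueError, match="collinear"):
            build_fir_design(ev, n_frames=20, n_lags=8)

    def test_event_outside_run_rejected(self):
        with pytest.raises(ValueError, match="fit within"):
            build_fir_design(events_df([15]), n_frames=20, n_lags=8)


class TestGlmFit:
    def test_noiseless_recovery_and_orthogonality(self, rng):
        d = build_fir_design(events_df([0, 10]), n_frames=40, n_lags=8,
                             blocks=[(0, 30)])
        true = rng.normal(size=(d.matrix.shape[1], 3))
        bold = BoldMatrix(d.matrix @ true, 2.2, "voxel")
        fit = fit_glm(bold, d)
        assert np.allclose(fit.betas, true, atol=1e-10)
        resid = bold.data - d.matrix @ fit.betas
        assert np.max(np.abs(d.matrix.T @ resid)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=(20, 4))
        from hippoparc.taskglm import FirDesign

        d = FirDesign(matrix=X, names=[f"c:lag{i}" for i in range(1, 7)],
                      conditions=["c"], n_lags=6)
        fit = fit_glm(BoldMatrix(y, 1.0, "voxel"), d)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.betas, oracle, atol=1e-8)

    def test_pure_noise_betas_small(self, rng):
        d = build_fir_design(events_df([5, 30, 60]), n_frames=100, n_lags=8)
        bold = BoldMatrix(rng.normal(size=(100, 50)), 2.2, "voxel")
        fit = fit_glm(bold, d)
        assert np.abs(fit.betas[:-1].mean()) < 0.2


class TestDeactivationContrast:
    def _session(self, amp, noise=0.0, seed=0, n_units=4):
        loadings = np.zeros((n_units, 4))
        loadings[: n_units // 2, 0] = 1.0  # DMN units
        loadings[n_units // 2:, 1] = 1.0   # PMN units
        spec = TaskSpec(n_frames=80, onsets={"task": [5, 30, 55]}, blocks=((2, 75),),
                        amplitudes={"DMN": amp, "PMN": 0.0}, noise_sd=noise, seed=seed)
        bold, events, _ = make_task_run(spec, loadings)
        design = build_fir_design(events, n_frames=80, n_lags=8, blocks=spec.blocks)
        return fit_glm(bold, design), loadings

    def test_injected_amplitude_recovered_exactly(self):
        fit, loadings = self._session(amp=-1.0)
        con = deactivation_contrast([fit])
        assert np.allclose(con.mean[loadings[:, 0] == 1], -1.0, atol=1e-8)
        assert np.allclose(con.mean[loadings[:, 1] == 1], 0.0, atol=1e-8)
        assert "single session" in con.flags[0]

    def test_contrast_is_linear_in_amplitude(self):
        c1 = deactivation_contrast([self._session(-1.0)[0]]).mean
        c2 = deactivation_contrast([self._session(-2.0)[0]]).mean
        assert np.allclose(c2, 2 * c1, atol=1e-8)

    def test_zero_amplitude_gives_zero(self):
        fit, _ = self._session(amp=0.0)
        con = deactivation_contrast([fit])
        assert np.allclose(con.mean, 0.0, atol=1e-10)

    def test_identical_sessions_zero_se_flagged(self):
        fit, _ = self._session(amp=-1.0)
        con = deactivation_contrast([fit, fit])
        assert any("zero across-session SE" in f for f in con.flags)
        assert np.isnan(con.z).all()

    def test_z_defined_with_noisy_sessions(self):
        fits = [self._session(-1.0, noise=0.3, seed=s)[0] for s in range(3)]
        con = deactivation_contrast(fits)
        assert con.n_sessions == 3
        assert np.isfinite(con.z).all()
        # DMN units robustly negative
        assert (con.z[:2] < -2).all()

    def test_include_cues_flag(self):
        spec = TaskSpec(n_frames=100, onsets={"cue_on": [5], "task": [30, 60]},
                        blocks=(), amplitudes={"DMN": -1.0, "PMN": 0.0},
                        noise_sd=0.0, seed=0)
        loadings = np.zeros((2, 4))
        loadings[0, 0] = 1.0
        loadings[1, 1] = 1.0
        bold, events, _ = make_task_run(spec, loadings)
        design = build_fir_design(events, n_frames=100, n_lags=8)
        fit = fit_glm(bold, design)
        with_cues = deactivation_contrast([fit], include_cues=True)
        without = deactivation_contrast([fit], include_cues=False)
        assert with_cues.mean[0] == pytest.approx(-1.0, abs=1e-8)
        assert without.mean[0] == pytest.approx(-1.0, abs=1e-8)


class TestRegionCompare:
    def test_single_subject_means_only(self):
        masks = {"DMN": np.array([True, False]), "PMN": np.array([False, True])}
        with pytest.warns(UserWarning, match="single subject"):
            res = region_deactivation_compare([np.array([-1.0, 0.0])], masks)
        assert res["p_value"] is None
        assert res["mean_DMN"] == -1.0

    def test_detects_dmn_specific_deactivation(self, rng):
        masks = {"DMN": np.r_[np.ones(10, bool), np.zeros(10, bool)],
                 "PMN": np.r_[np.zeros(10, bool), np.ones(10, bool)]}
        maps = [np.r_[rng.normal(-1.0, 0.1, 10), rng.normal(0.0, 0.1, 10)]
                for _ in range(6)]
        res = region_deactivation_compare(maps, masks, n_flips=10000, seed=0)
        assert res["mean_DMN"] < res["mean_PMN"]
        assert res["p_value"] <= 0.05

    def test_empty_scope_errors(self):
        masks = {"DMN": np.array([True, False]), "PMN": np.array([False, True])}
        with pytest.raises(ValueError, match="empty within"):
            region_deactivation_compare([np.zeros(2)], masks,
                                        scope_mask=np.array([False, False]))

    def test_deterministic_given_seed(self, rng):
        masks = {"DMN": np.array([True, False]), "PMN": np.array([False, True])}
        maps = [rng.normal(size=2) for _ in range(5)]
        a = region_deactivation_compare(maps, masks, seed=7)
        b = region_deactivation_compare(maps, masks, seed=7)
        assert a["p_value"] == b["p_value"]
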