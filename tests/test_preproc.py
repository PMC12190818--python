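"""BOLD correction, percent signal change, and the block GLM."""

import numpy as np
import pandas as pd
import pytest

from lamsal.design import condition_regressors, make_block_design
from lamsal.preproc import (DesignError, boco_correct, build_design_matrix,
                            condition_responses, fit_glm,
                            percent_signal_change, split_and_align)
from lamsal.synth import LaminarSeries, ScenarioSpec, simulate_vaso_session


def series_from_functions(design, f_nulled, f_notnulled):
    """Interleaved series whose streams sample two continuous functions."""
    t = design.frame_times()
    labels = design.frame_labels()
    data = np.where(labels == "nulled", f_nulled(t), f_notnulled(t))[None, :]
    return LaminarSeries(data=data, frame_labels=labels, frame_times=t,
                         meta={"frames_per_run": design.frames_per_run,
                               "pair_tr": design.pair_tr,
                               "frame_interval": design.frame_interval})


@pytest.fixture(scope="module")
def design1():
    return make_block_design(1)


class TestSplitAndAlign:
    def test_constant_series_stays_constant(self, design1):
        s = series_from_functions(design1, lambda t: 5.0 + 0 * t,
                                  lambda t: 7.0 + 0 * t)
        nulled, notnulled = split_and_align(s)
        assert np.allclose(nulled.data, 5.0)
        assert np.allclose(notnulled.data, 7.0)

    def test_linear_ramp_reproduced_exactly(self, design1):
        ramp = lambda t: 2.0 + 0.03 * t
        s = series_from_functions(design1, ramp, ramp)
        nulled, notnulled = split_and_align(s)
        t = nulled.times
        # exact on the interior; the very last/first sample of each stream is
        # edge-held
        assert np.allclose(nulled.data[0, :-1], ramp(t[:-1]), atol=1e-12)
        assert np.allclose(notnulled.data[0, 1:], ramp(t[1:]), atol=1e-12)

    def test_slow_sinusoid_interpolation_error_below_2_percent(self, design1):
        tr = design1.pair_tr
        f = 1.0 / (8.0 * tr)
        sig = lambda t: np.sin(2 * np.pi * f * t)
        s = series_from_functions(design1, sig, sig)
        nulled, _ = split_and_align(s)
        err = nulled.data[0, 1:-1] - sig(nulled.times[1:-1])
        rms_rel = np.sqrt(np.mean(err ** 2)) / np.sqrt(np.mean(sig(nulled.times) ** 2))
        assert rms_rel < 0.02

    def test_non_alternating_labels_rejected(self, design1):
        s = series_from_functions(design1, lambda t: t, lambda t: t)
        bad = s.frame_labels.copy()
        bad[2], bad[3] = bad[3], bad[2]
        with pytest.raises(ValueError):
            split_and_align(LaminarSeries(s.data, bad, s.frame_times, s.meta))


class TestBoco:
    def test_identical_streams_give_unit_ratio(self, design1):
        slow = lambda t: 100 + 0.5 * np.sin(2 * np.pi * t / 200.0)
        s = series_from_functions(design1, slow, slow)
        nulled, notnulled = split_and_align(s)
        ratio = boco_correct(nulled, notnulled)
        assert np.allclose(ratio.data[0, 1:-1], 1.0, atol=1e-5)
        # and exactly 1 for constant streams
        s2 = series_from_functions(design1, lambda t: 80 + 0 * t,
                                   lambda t: 80 + 0 * t)
        r2 = boco_correct(*split_and_align(s2))
        assert np.allclose(r2.data, 1.0, atol=1e-14)

    def test_scale_invariance(self, design1):
        f, g = lambda t: 100 - 0.5 * np.sin(t / 40), lambda t: 100 + 0 * t
        s1 = series_from_functions(design1, f, g)
        s2 = series_from_functions(design1, lambda t: 2 * f(t), lambda t: 2 * g(t))
        r1 = boco_correct(*split_and_align(s1))
        r2 = boco_correct(*split_and_align(s2))
        assert np.allclose(r1.data, r2.data)

    def test_nonpositive_denominator_masks_voxel(self, design1):
        s = series_from_functions(design1, lambda t: 100 + 0 * t,
                                  lambda t: 100 + 0 * t)
        s.data[0, 1] = -1.0   # one bad not-nulled frame
        nulled, notnulled = split_and_align(s)
        with pytest.warns(UserWarning, match="non-positive"):
            ratio = boco_correct(nulled, notnulled)
        assert np.isnan(ratio.data[0]).all()


class TestPercentSignalChange:
    def test_constant_maps_to_zero(self):
        data = np.full((3, 40), 7.0)
        runs = np.repeat([0, 1], 20)
        assert np.allclose(percent_signal_change(data, runs), 0.0)

    def test_boxcar_construction(self):
        box = np.zeros(50)
        box[10:20] = 1.0
        data = 200.0 * (1 + 0.01 * box)[None, :]
        out = percent_signal_change(data, np.zeros(50, dtype=int))
        # 1% during blocks up to the run-mean baseline scale (mean includes
        # the blocks themselves)
        assert out[0, 10:20].mean() - out[0, 0] == pytest.approx(1.0, rel=5e-3)

    def test_run_means_are_zero(self):
        rng = np.random.default_rng(0)
        data = 100 + rng.normal(size=(4, 60))
        runs = np.repeat([0, 1, 2], 20)
        out = percent_signal_change(data, runs)
        for r in range(3):
            assert np.allclose(out[:, runs == r].mean(axis=1), 0.0, atol=1e-10)


class TestGLM:
    def test_noiseless_regressor_recovered_exactly(self, design1):
        t = design1.frame_times()[::2]
        runs = np.zeros(t.size, dtype=int)
        X, names = build_design_matrix(t, design1, runs)
        y = 3.0 * X[:, names.index("theta90")]
        glm = fit_glm(y[None, :], X, names)
        assert glm.betas.loc[0, "theta90"] == pytest.approx(3.0, abs=1e-9)
        assert glm.betas.loc[0, "theta15"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_absorbed_by_intercept(self, design1):
        t = design1.frame_times()[::2]
        runs = np.zeros(t.size, dtype=int)
        X, names = build_design_matrix(t, design1, runs)
        rng = np.random.default_rng(1)
        y = rng.normal(size=t.size)
        b0 = fit_glm(y[None, :], X, names).betas
        b1 = fit_glm(y[None, :] + 10.0, X, names).betas
        diff = (b1 - b0).abs()
        assert diff.loc[0, "run0_drift0"] == pytest.approx(10.0)
        assert diff.drop(columns="run0_drift0").to_numpy().max() < 1e-9

    def test_rank_deficient_design_names_columns(self, design1):
        t = design1.frame_times()[::2]
        runs = np.zeros(t.size, dtype=int)
        X, names = build_design_matrix(t, design1, runs)
        X = np.column_stack([X, X[:, 0]])
        names = names + ["dup"]
        with pytest.raises(DesignError, match="dup"):
            fit_glm(np.zeros((1, t.size)), X, names)

    def test_white_noise_beta_sd_matches_ols_theory(self, design1):
        t = design1.frame_times()[::2]
        runs = np.zeros(t.size, dtype=int)
        X, names = build_design_matrix(t, design1, runs)
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(2000, t.size))       # 2000 null replicates
        glm = fit_glm(Y, X, names)
        j = names.index("theta90")
        theory = np.sqrt(np.linalg.inv(X.T @ X)[j, j])
        emp = glm.betas["theta90"].std()
        assert emp == pytest.approx(theory, rel=0.10)
        assert abs(glm.betas["theta90"].mean()) < 3 * theory / np.sqrt(2000)


class TestFullChain:
    def test_gain_scaling_scales_betas(self, single_voxel_model, design_two_runs,
                                       noiseless_v1sh):
        base = noiseless_v1sh
        resp1 = condition_responses(
            simulate_vaso_session(single_voxel_model, design_two_runs, base),
            design_two_runs)["betas"]
        scaled = base.zeroed()
        for reg in scaled.gains:
            scaled.gains[reg] = {th: 2.0 * np.asarray(g)
                                 for th, g in base.gains[reg].items()}
        resp2 = condition_responses(
            simulate_vaso_session(single_voxel_model, design_two_runs, scaled),
            design_two_runs)["betas"]
        assert np.allclose(resp2.to_numpy(), 2.0 * resp1.to_numpy(), atol=1e-9)

    def test_boco_removes_simulated_bold_contamination(
            self, single_voxel_model, design_two_runs, noiseless_v1sh):
        """Multiplicative BOLD contamination shared by both streams leaves
        the CBV condition beta equal to the uncontaminated one (< 1e-3 %)."""
        clean = noiseless_v1sh
        clean.bold_ratio = 0.0
        contaminated = ScenarioSpec.default("v1sh", noise_sd=0.0,
                                            drift_amp=0.0, bold_ratio=0.7)
        b_clean = condition_responses(
            simulate_vaso_session(single_voxel_model, design_two_runs, clean),
            design_two_runs)["betas"]
        b_cont = condition_responses(
            simulate_vaso_session(single_voxel_model, design_two_runs,
                                  contaminated),
            design_two_runs)["betas"]
        assert np.abs(b_cont.to_numpy() - b_clean.to_numpy()).max() < 1e-3
        # and the not-nulled stream does carry the BOLD response
        bold = condition_responses(
            simulate_vaso_session(single_voxel_model, design_two_runs,
                                  contaminated),
            design_two_runs, stream="bold")["betas"]
        assert bold.loc[0, "90"] == pytest.approx(0.7, abs=1e-6)
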