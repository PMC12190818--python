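"""Normalization, repeated-measures ANOVA, paired tests, permutation FWE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from lamsal.stats import (brain_behavior_correlation, holm_correct,
                          normalize_responses, paired_t, rm_anova_one_way,
                          rm_anova_two_way, saliency_sensitive_response,
                          strongest_layer)


class TestNormalization:
    def test_uniform_subject_is_fixed_point(self):
        norm = normalize_responses(np.full((1, 3, 3), 2.0))
        assert norm.rnorm[0] == pytest.approx(2.0)
        assert norm.rbar == pytest.approx(2.0)
        assert np.allclose(norm.s_fmri, 2.0)

    def test_per_subject_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(size=(1, 3, 3))
        both = np.concatenate([a, 2.0 * a])
        norm = normalize_responses(both)
        assert np.allclose(norm.s_fmri[0], norm.s_fmri[1], atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rms_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(1.0, 0.7, size=(20, 3, 3))
        norm = normalize_responses(r)
        rms = np.sqrt((norm.s_fmri ** 2).mean(axis=(1, 2)))
        assert np.allclose(rms, norm.rbar, atol=1e-9)

    def test_all_zero_subject_rejected(self):
        r = np.ones((3, 3, 3))
        r[1] = 0.0
        with pytest.raises(ValueError, match="normalization"):
            normalize_responses(r)

    def test_saliency_sensitive_difference(self):
        r = np.zeros((2, 3, 3))
        r[:, :, 0] = 1.2   # theta 90
        r[:, :, 1] = 0.9   # theta 15
        r[:, :, 2] = 0.1
        norm = normalize_responses(r)
        ss = saliency_sensitive_response(norm)
        expected = norm.s_fmri[:, :, 0] - norm.s_fmri[:, :, 1]
        assert np.allclose(ss, expected)
        assert np.all(ss > 0)

    def test_strongest_layer_subject_order_invariant(self):
        rng = np.random.default_rng(1)
        ss = rng.normal(size=(15, 3))
        assert strongest_layer(ss) == strongest_layer(ss[::-1])


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(12, 2))
        res = rm_anova_one_way(y, correction="never")
        t = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res["F"] == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert res["p"] == pytest.approx(t.pvalue, abs=1e-12)

    def test_one_way_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
        res = rm_anova_one_way(y)
        long = pd.DataFrame({"subject": np.repeat(np.arange(10), 4),
                             "cond": np.tile(np.arange(4), 10),
                             "y": y.ravel()})
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          correction=True)
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res["epsilon"] == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)

    def test_type_one_error_calibration(self):
        """Null simulations reject at ~alpha with the sphericity-gated p."""
        rng = np.random.default_rng(4)
        n_sims, n_rej = 10_000, 0
        for _ in range(n_sims):
            y = rng.normal(size=(10, 3))
            n_rej += rm_anova_one_way(y)["p_selected"] < 0.05
        assert 0.04 <= n_rej / n_sims <= 0.06

    def test_subject_constant_does_not_change_f(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(8, 3, 3))
        shifted = y + rng.normal(size=(8, 1, 1))
        tab_a = rm_anova_two_way(y)
        tab_b = rm_anova_two_way(shifted)
        assert np.allclose(tab_a["F"].to_numpy(), tab_b["F"].to_numpy(), atol=1e-9)

    def test_two_way_missing_cells_rejected(self):
        y = np.ones((5, 3, 3))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_two_way(y)


class TestPairedTAndHolm:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_holm_stepdown_hand_example(self):
        assert np.allclose(holm_correct([0.01, 0.04]), [0.02, 0.04])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_holm_bounds_and_monotonicity(self, pvals):
        adj = holm_correct(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBrainBehaviorCorrelation:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        out = brain_behavior_correlation(x[:, None], x, n_perm=500, seed=0)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p_fwe"].iloc[0] < 0.05

    def test_single_roi_fwe_equals_raw(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 1))
        y = rng.normal(size=15)
        out = brain_behavior_correlation(X, y, n_perm=2000, seed=1)
        assert out["p_fwe"].iloc[0] == pytest.approx(out["p_raw"].iloc[0],
                                                     abs=1e-12)

    def test_fwe_p_never_below_raw(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(18, 3))
        y = rng.normal(size=18)
        out = brain_behavior_correlation(X, y, n_perm=1000, seed=2)
        assert np.all(out["p_fwe"].to_numpy() >= out["p_raw"].to_numpy() - 1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            brain_behavior_correlation(np.ones((10, 2)), np.arange(10.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5"):
            brain_behavior_correlation(np.random.rand(4, 2), np.arange(4.0))
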