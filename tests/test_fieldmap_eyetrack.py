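"""Visual-field reconstruction from pRFs and gaze-stability metrics."""

import numpy as np
import pandas as pd
import pytest

from lamsal.eyetrack import bcea, bcea_k, preprocess_gaze
from lamsal.fieldmap import (align_prf_to_localizer, field_grid,
                             normalize_fieldmaps, reconstruct_by_depth,
                             reconstruct_fieldmap)
from lamsal.synth import simulate_gaze


def nodes_df(x0, y0, sigma, response, layer=None):
    df = pd.DataFrame({"x0": x0, "y0": y0, "sigma": sigma, "response": response})
    if layer is not None:
        df["layer"] = layer
    return df


class TestReconstruction:
    def test_single_node_peaks_at_its_center(self):
        gx, gy = field_grid(step=0.1)
        m = reconstruct_fieldmap(nodes_df([2.0], [-3.0], [1.0], [1.0]), gx, gy)
        iy, ix = np.unravel_index(np.argmax(m), m.shape)
        assert gx[ix] == pytest.approx(2.0, abs=0.051)
        assert gy[iy] == pytest.approx(-3.0, abs=0.051)

    def test_symmetric_nodes_give_symmetric_map(self):
        gx, gy = field_grid(x_range=(-4, 4), step=0.1)
        m = reconstruct_fieldmap(
            nodes_df([-2.0, 2.0], [-3.0, -3.0], [1.0, 1.0], [1.0, 1.0]), gx, gy)
        assert np.allclose(m, m[:, ::-1], atol=1e-12)

    def test_zero_responses_give_zero_map(self):
        gx, gy = field_grid(step=0.5)
        m = reconstruct_fieldmap(nodes_df([1.0], [-1.0], [1.0], [0.0]), gx, gy)
        assert np.allclose(m, 0.0)

    def test_linearity_in_responses(self):
        gx, gy = field_grid(step=0.5)
        nodes = nodes_df([1.0, -2.0], [-1.0, -4.0], [0.8, 1.5], [0.7, -0.3])
        scaled = nodes.assign(response=3.0 * nodes.response)
        assert np.allclose(reconstruct_fieldmap(scaled, gx, gy),
                           3.0 * reconstruct_fieldmap(nodes, gx, gy), atol=1e-12)

    def test_hotspot_peak_recovered_within_grid_step(self):
        """pRFs tiling the lower field with responses from a Gaussian hotspot
        at the foreground location reproduce the hotspot peak."""
        cx, cy = 4.3 / np.sqrt(2), -4.3 / np.sqrt(2)
        xg, yg = np.meshgrid(np.arange(-8, 8.01, 0.5), np.arange(-8, 0.01, 0.5))
        x0, y0 = xg.ravel(), yg.ravel()
        resp = np.exp(-((x0 - cx) ** 2 + (y0 - cy) ** 2) / (2 * 1.5 ** 2))
        gx, gy = field_grid(step=0.1)
        m = reconstruct_fieldmap(nodes_df(x0, y0, np.full(x0.size, 1.0), resp),
                                 gx, gy)
        iy, ix = np.unravel_index(np.argmax(m), m.shape)
        assert abs(gx[ix] - cx) <= 0.1 + 1e-9
        assert abs(gy[iy] - cy) <= 0.1 + 1e-9

    def test_empty_nodes_rejected(self):
        gx, gy = field_grid(step=0.5)
        with pytest.raises(ValueError, match="empty"):
            reconstruct_fieldmap(nodes_df([], [], [], []), gx, gy)


class TestNormalization:
    def test_dominant_depth_peaks_at_one(self):
        gx, gy = field_grid(step=0.5)
        nodes = nodes_df([0.0, 0.0], [-2.0, -2.0], [1.0, 1.0], [2.0, 0.5],
                         layer=["superficial", "deep"])
        maps = reconstruct_by_depth(nodes, gx, gy)
        group = normalize_fieldmaps([maps])
        assert group["superficial"].max() == pytest.approx(1.0)
        assert group["deep"].max() < 1.0

    def test_global_scale_invariance(self):
        gx, gy = field_grid(step=0.5)
        nodes = nodes_df([0.0, 1.0], [-2.0, -3.0], [1.0, 1.0], [2.0, 0.5],
                         layer=["superficial", "deep"])
        maps = reconstruct_by_depth(nodes, gx, gy)
        scaled = {d: 5.0 * m for d, m in maps.items()}
        a = normalize_fieldmaps([maps])
        b = normalize_fieldmaps([scaled])
        for d in a:
            assert np.allclose(a[d], b[d], atol=1e-12)

    def test_nonpositive_maximum_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            normalize_fieldmaps([{"deep": np.zeros((3, 3))}])


class TestAlignment:
    def test_identity_when_peak_on_target(self):
        nodes = nodes_df([1.0], [-1.0], [1.0], [1.0])
        out = align_prf_to_localizer(nodes, (3.0, -3.0), (3.0, -3.0))
        pd.testing.assert_frame_equal(out, nodes)

    def test_translation(self):
        nodes = nodes_df([1.0, 2.0], [-1.0, -2.0], [1.0, 1.0], [1.0, 1.0])
        out = align_prf_to_localizer(nodes, (4.0, -3.5), (3.0, -3.0))
        assert np.allclose(out.x0, nodes.x0 - 1.0)
        assert np.allclose(out.y0, nodes.y0 + 0.5)

    def test_idempotent(self):
        nodes = nodes_df([1.0], [-1.0], [1.0], [1.0])
        once = align_prf_to_localizer(nodes, (4.0, -3.0), (3.0, -3.0))
        twice = align_prf_to_localizer(once, (3.0, -3.0), (3.0, -3.0))
        pd.testing.assert_frame_equal(once, twice)

    def test_flat_localizer_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            align_prf_to_localizer(nodes_df([0.0], [0.0], [1.0], [1.0]),
                                   (np.nan, np.nan), (3.0, -3.0))


class TestPreprocessGaze:
    def test_baseline_correction_zeroes_block_means(self):
        trace = simulate_gaze(5000, blink_rate=0.0, seed=0)
        trace.loc[2500:, "block"] = 1
        clean = preprocess_gaze(trace)
        for _, blk in clean.groupby("block"):
            assert abs(blk.x.mean()) < 1e-10 and abs(blk.y.mean()) < 1e-10

    def test_pure_linear_drift_removed(self):
        t = np.arange(3000, dtype=float)
        trace = pd.DataFrame({"time": t, "x": 0.001 * t, "y": -0.0005 * t,
                              "valid": True, "block": 0})
        clean = preprocess_gaze(trace)
        assert np.abs(clean.x).max() < 1e-9
        assert np.abs(clean.y).max() < 1e-9

    def test_blink_interpolation_recovers_linear_segment(self):
        t = np.arange(2000, dtype=float)
        x = 1.0 + 0.002 * t
        valid = np.ones(2000, dtype=bool)
        valid[900:1000] = False     # 100 ms blink
        trace = pd.DataFrame({"time": t, "x": np.where(valid, x, np.nan),
                              "y": np.where(valid, x, np.nan),
                              "valid": valid, "block": 0})
        clean = preprocess_gaze(trace)
        detrended = x - np.polyval(np.polyfit(t, x, 1), t)
        assert np.allclose(clean.x, detrended - detrended.mean(), atol=1e-9)

    def test_fully_invalid_block_dropped(self):
        trace = simulate_gaze(2000, blink_rate=0.0, seed=1)
        trace.loc[:999, "valid"] = False
        trace.loc[:999, "block"] = 1
        with pytest.warns(UserWarning, match="dropped"):
            clean = preprocess_gaze(trace)
        assert set(clean.block) == {0}


class TestBcea:
    def test_closed_form_unit_isotropic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50_000)
        y = rng.normal(size=50_000)
        expected = 2 * np.pi * bcea_k(0.95)     # ~18.82 deg^2
        assert expected == pytest.approx(18.82, abs=0.01)
        assert bcea(x, y) == pytest.approx(expected, rel=0.02)

    def test_degenerate_correlation_shrinks_area(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        for rho in (0.9, 0.99, 0.999):
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=5000)
            expected = 2 * np.pi * bcea_k(0.95) * np.sqrt(1 - np.corrcoef(x, y)[0, 1] ** 2)
            assert bcea(x, y) == pytest.approx(expected, rel=0.05)
        assert bcea(x, x + 0.0) == pytest.approx(0.0, abs=1e-5)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        x = 2.0 * rng.normal(size=20_000)
        y = 0.5 * rng.normal(size=20_000)
        th = 0.7
        xr = np.cos(th) * x - np.sin(th) * y
        yr = np.sin(th) * x + np.cos(th) * y
        assert bcea(xr, yr) == pytest.approx(bcea(x, y), rel=1e-9)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        assert bcea(3 * x, 3 * y) == pytest.approx(9 * bcea(x, y), rel=1e-9)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero"):
            assert bcea(np.zeros(20), np.ones(20)) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bcea(np.arange(5.0), np.arange(5.0))
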