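"""Visual-field reconstruction of saliency signals from pRF models.

Each surface node carries an isotropic 2D Gaussian population receptive
field (center x0, y0; size sigma, degrees of visual angle) and a saliency-
sensitive response; the field map at a cortical depth is the response-
weighted sum of the node pRFs over a visual-field lattice.  Maps are
normalized by the single maximum across depths (so depth maps remain
comparable) before group averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["field_grid", "reconstruct_fieldmap", "reconstruct_by_depth",
           "normalize_fieldmaps", "align_prf_to_localizer"]


def field_grid(x_range=(-8.0, 8.0), y_range=(-8.0, 0.0), step: float = 0.1):
    """Default lower-visual-field lattice; returns (x, y) 1D coordinate arrays."""
    x = np.arange(x_range[0], x_range[1] + step / 2, step)
    y = np.arange(y_range[0], y_range[1] + step / 2, step)
    return x, y


def reconstruct_fieldmap(nodes: pd.DataFrame, grid_x: np.ndarray,
                         grid_y: np.ndarray,
                         normalize_prf: bool = False) -> np.ndarray:
    """Sum of response-weighted Gaussian pRFs on the lattice.

    ``nodes`` columns: x0, y0, sigma, response.  Returns map (ny, nx) with
    map[iy, ix] = sum_n resp_n * exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2)); with
    ``normalize_prf`` each pRF integrates to 1 instead of peaking at 1.
    """
    if len(nodes) == 0:
        raise ValueError("empty node set")
    gx = np.asarray(grid_x)[None, :, None]
    gy = np.asarray(grid_y)[:, None, None]
    x0 = nodes["x0"].to_numpy()[None, None, :]
    y0 = nodes["y0"].to_numpy()[None, None, :]
    sig = nodes["sigma"].to_numpy()[None, None, :]
    if np.any(nodes["sigma"].to_numpy() <= 0):
        raise ValueError("pRF sizes must be positive")
    resp = nodes["response"].to_numpy()[None, None, :]
    g = np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) / (2.0 * sig ** 2))
    if normalize_prf:
        g = g / (2.0 * np.pi * sig ** 2)
    return (g * resp).sum(axis=2)


def reconstruct_by_depth(nodes: pd.DataFrame, grid_x, grid_y,
                         depth_column: str = "layer",
                         normalize_prf: bool = False) -> dict:
    """One reconstructed map per cortical depth label."""
    return {d: reconstruct_fieldmap(sub, grid_x, grid_y, normalize_prf)
            for d, sub in nodes.groupby(depth_column, sort=False, observed=True)}


def normalize_fieldmaps(maps_per_subject: list[dict]) -> dict:
    """Normalize each subject's depth maps by that subject's maximum across
    all depths, then average across subjects."""
    if not maps_per_subject:
        raise ValueError("no maps given")
    depths = list(maps_per_subject[0])
    acc = {d: [] for d in depths}
    for maps in maps_per_subject:
        peak = max(float(np.max(maps[d])) for d in depths)
        if peak <= 0:
            raise ValueError("non-positive global maximum: cannot normalize")
        for d in depths:
            acc[d].append(maps[d] / peak)
    return {d: np.mean(acc[d], axis=0) for d in depths}


def align_prf_to_localizer(nodes: pd.DataFrame, localizer_peak,
                           foreground_center) -> pd.DataFrame:
    """Translate all pRF centers so the localizer activation peak lands on
    the true foreground location (per-subject retinotopic alignment)."""
    peak = np.asarray(localizer_peak, dtype=float)
    target = np.asarray(foreground_center, dtype=float)
    if not np.all(np.isfinite(peak)):
        raise ValueError("undefined localizer peak")
    shift = target - peak
    out = nodes.copy()
    out["x0"] = out["x0"] + shift[0]
    out["y0"] = out["y0"] + shift[1]
    return out
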