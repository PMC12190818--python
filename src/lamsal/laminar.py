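"""Equi-volume cortical depths, layer-weight unmixing, and ROI selection.

Cortical grey matter between the white-matter (WM) and pial surfaces is
divided into three compartments — deep, middle, superficial — using the
equi-volume principle: boundaries are placed so each compartment holds the
same cortical volume, which compensates for cortical curvature (layers are
thicker on gyral crowns where the pial circumference is larger).  The package
models a cortical patch parametrically as an annular wedge (2D) or spherical
shell (3D) so the geometry has closed-form boundaries that can be checked by
brute-force integration.

Voxel responses are a partial-volume mixture of compartment responses;
``unmix_layers`` inverts that mixture by least squares over the voxel
layer-weight matrix, with WM and CSF treated as nuisance compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["COMPARTMENTS", "GM_LAYERS", "equivolume_boundaries",
           "unmix_layers", "select_foreground_roi", "roi_layer_profile",
           "UnmixingError"]

COMPARTMENTS = ("wm", "csf", "deep", "middle", "superficial")
GM_LAYERS = ("deep", "middle", "superficial")


class UnmixingError(ValueError):
    pass


def equivolume_boundaries(wm_radius: float, pial_radius: float,
                          fractions=(1.0 / 3.0, 2.0 / 3.0),
                          model: str = "annulus2d") -> np.ndarray:
    """Radii of equi-volume laminar boundaries.

    ``fractions`` are cumulative cortical-volume fractions measured from the
    WM surface.  For the 2D annulus the boundary enclosing fraction ``a`` of
    the cortical ring area is ``r(a) = sqrt(a*pial^2 + (1-a)*wm^2)``; the 3D
    spherical shell replaces squares by cubes.
    """
    if not (0 < wm_radius < pial_radius):
        raise ValueError("require 0 < wm_radius < pial_radius")
    alpha = np.asarray(fractions, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if model == "annulus2d":
        return np.sqrt(alpha * pial_radius ** 2 + (1 - alpha) * wm_radius ** 2)
    if model == "sphere3d":
        return np.cbrt(alpha * pial_radius ** 3 + (1 - alpha) * wm_radius ** 3)
    raise ValueError(f"unknown geometry model {model!r}")


def unmix_layers(voxel_betas: np.ndarray, weights: np.ndarray,
                 compartments=COMPARTMENTS) -> dict:
    """Least-squares spatial unmixing of voxel responses into compartments.

    Parameters
    ----------
    voxel_betas : (n_voxels,) or (n_voxels, k) response estimates
    weights : (n_voxels, n_compartments) partial-volume weight matrix

    Returns a dict with ``betas`` (n_compartments, k) — NaN for compartments
    with no volume support — and ``layers`` (3, k), the grey-matter rows in
    deep → superficial order.
    """
    y = np.atleast_2d(np.asarray(voxel_betas, dtype=float).T).T
    W = np.asarray(weights, dtype=float)
    if W.shape[0] != y.shape[0]:
        raise UnmixingError("voxel_betas and weights have different voxel counts")
    represented = W.sum(axis=0) > 1e-12
    Wr = W[:, represented]
    if Wr.shape[0] < Wr.shape[1]:
        raise UnmixingError("fewer voxels than represented compartments")
    rank = np.linalg.matrix_rank(Wr)
    if rank < Wr.shape[1]:
        # name the compartments involved in the collinearity
        _, s, vt = np.linalg.svd(Wr)
        bad = np.abs(vt[rank:]).sum(axis=0) > 1e-9
        names = [c for c, r, b in zip(compartments, represented, _expand(bad, represented))
                 if r and b]
        raise UnmixingError(f"unidentifiable compartments: {names}")
    sol, *_ = np.linalg.lstsq(Wr, y, rcond=None)
    betas = np.full((W.shape[1], y.shape[1]), np.nan)
    betas[represented] = sol
    idx = [compartments.index(l) for l in GM_LAYERS]
    return {"betas": betas, "layers": betas[idx], "compartments": list(compartments)}


def _expand(bad, represented):
    out, j = [], 0
    for r in represented:
        out.append(bad[j] if r else False)
        j += bool(r)
    return out


def select_foreground_roi(localizer_betas: np.ndarray, localizer_se: np.ndarray,
                          dof: int, region_labels: np.ndarray, region: str,
                          p_threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of voxels with positive localizer activation.

    One-sided t-test per voxel (beta / se against 0, uncorrected) intersected
    with the anatomical region; an empty result is returned with a warning
    rather than raised.
    """
    beta = np.asarray(localizer_betas, dtype=float)
    se = np.asarray(localizer_se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = sps.t.sf(t, dof)
    mask = (p < p_threshold) & (beta > 0) & (np.asarray(region_labels) == region)
    if not mask.any():
        warnings.warn(f"empty foreground ROI in region {region!r}")
    return mask


def roi_layer_profile(condition_betas: np.ndarray, weights: np.ndarray,
                      roi_mask: np.ndarray) -> np.ndarray:
    """Layer x condition response profile for one ROI.

    ``condition_betas`` is (n_voxels, n_conditions); returns (3, n_conditions)
    in deep → superficial order by unmixing over the ROI voxels.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise UnmixingError("empty ROI")
    res = unmix_layers(np.asarray(condition_betas)[roi_mask],
                       np.asarray(weights)[roi_mask])
    return res["layers"]
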