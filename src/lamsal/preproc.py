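"""BOLD-corrected CBV responses from interleaved VASO acquisitions.

The chain mirrors standard laminar-VASO preprocessing: the alternating
blood-nulled / not-nulled frames are separated, temporally up-sampled by a
factor of two onto a common grid (the lagging stream is thereby shifted by
TR/2), the nulled stream is divided by the not-nulled stream to cancel the
shared T2* (BOLD) component ("BOLD correction"), each run is scaled to
percent signal change around its mean, and a GLM with HRF-convolved block
regressors plus per-run Legendre drifts estimates condition amplitudes.
Activation lowers the nulled signal, so the CBV response is reported as the
negated VASO percent change (positive during activation).

Two numerical choices matter for amplitude fidelity and are documented in
docs/methods.md: condition betas are estimated at each stream's native
(paired-TR) timepoints, and the multiplicative bias introduced by run-mean
scaling is removed in closed form (``mean-scale correction``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlockDesign, condition_regressors
from .resample import fill_alternate
from .synth import LaminarSeries

__all__ = ["SampledSeries", "GLMResult", "split_and_align", "boco_correct",
           "percent_signal_change", "build_design_matrix", "fit_glm",
           "condition_responses", "DesignError"]


class DesignError(ValueError):
    pass


@dataclass
class SampledSeries:
    """Voxel x time matrix on a single (non-interleaved) time grid."""

    data: np.ndarray
    times: np.ndarray
    run_index: np.ndarray
    native: np.ndarray      # True where the sample was acquired, not interpolated
    meta: dict


def split_and_align(series: LaminarSeries) -> tuple[SampledSeries, SampledSeries]:
    """Separate nulled and not-nulled frames and up-sample both onto the
    common (TR/2) frame grid, aligning the lagging stream by half a TR."""
    labels = np.asarray(series.frame_labels)
    if not np.all(labels[::2] == labels[0]) or not np.all(labels[1::2] == labels[1]) \
            or labels[0] == labels[1]:
        raise DesignError("frame labels must strictly alternate")
    fpr = series.meta.get("frames_per_run", labels.size)
    runs = np.repeat(np.arange(labels.size // fpr), fpr)
    out = []
    for name in ("nulled", "notnulled"):
        have = labels == name
        values = np.where(have, series.data, np.nan)
        data = fill_alternate(values, have, runs)
        out.append(SampledSeries(data=data, times=np.asarray(series.frame_times),
                                 run_index=runs, native=have,
                                 meta=dict(series.meta, stream=name)))
    return tuple(out)


def boco_correct(nulled: SampledSeries, notnulled: SampledSeries) -> SampledSeries:
    """BOLD correction: element-wise ratio of nulled over not-nulled signal.

    Voxels with a non-positive denominator anywhere are masked (NaN) with a
    warning; the ratio is dimensionless with baseline ~1.
    """
    if nulled.data.shape != notnulled.data.shape:
        raise DesignError("streams must share one time grid")
    denom = notnulled.data
    bad = ~(denom > 0)
    if bad.any():
        n_vox = int(np.unique(np.nonzero(bad)[0]).size)
        warnings.warn(f"non-positive not-nulled signal: masking {n_vox} voxel(s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, nulled.data / np.where(bad, 1.0, denom))
    ratio[bad.any(axis=1)] = np.nan
    return SampledSeries(data=ratio, times=nulled.times, run_index=nulled.run_index,
                         native=nulled.native, meta=dict(nulled.meta, stream="vaso"))


def percent_signal_change(data: np.ndarray, run_index: np.ndarray) -> np.ndarray:
    """Per-run scaling to percent change around the run-mean baseline."""
    data = np.asarray(data, dtype=float)
    out = np.empty_like(data)
    for r in np.unique(run_index):
        cols = run_index == r
        base = data[:, cols].mean(axis=1, keepdims=True)
        zero = np.abs(base) < 1e-12
        if zero.any():
            warnings.warn(f"zero baseline in run {r}: masking {int(zero.sum())} voxel(s)")
        base = np.where(zero, np.nan, base)
        out[:, cols] = 100.0 * (data[:, cols] - base) / base
    return out


def build_design_matrix(times: np.ndarray, design: BlockDesign,
                        run_index: np.ndarray, drift_order: int = 3,
                        motion: np.ndarray | None = None
                        ) -> tuple[np.ndarray, list[str]]:
    """GLM design: HRF-convolved condition regressors, per-run Legendre
    drifts up to ``drift_order`` (order 0 = per-run intercept), and optional
    motion columns."""
    regs = condition_regressors(design, times)
    cols = [np.asarray(regs[c]) for c in design.conditions]
    names = [f"theta{c}" for c in design.conditions]
    for r in np.unique(run_index):
        sel = run_index == r
        x = np.linspace(-1.0, 1.0, int(sel.sum()))
        for k in range(drift_order + 1):
            col = np.zeros_like(times, dtype=float)
            col[sel] = np.polynomial.legendre.Legendre.basis(k)(x)
            cols.append(col)
            names.append(f"run{r}_drift{k}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float).T).T
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion{j}")
    return np.column_stack(cols), names


@dataclass
class GLMResult:
    betas: pd.DataFrame        # voxel x regressor
    se: pd.DataFrame           # standard error of each beta
    resid_var: np.ndarray      # per-voxel residual variance
    dof: int
    design_matrix: np.ndarray
    names: list


def fit_glm(data: np.ndarray, X: np.ndarray, names: list[str]) -> GLMResult:
    """Ordinary least squares, voxel-wise; raises ``DesignError`` naming the
    collinear columns when the design matrix is rank deficient."""
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.shape[0] != Y.shape[1]:
        raise DesignError("design matrix and data have different time lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.abs(vt[rank:]).sum(axis=0) > 1e-9
        raise DesignError("rank-deficient design; collinear columns: "
                          f"{[n for n, b in zip(names, bad) if b]}")
    valid = ~np.isnan(Y).any(axis=1)
    B = np.full((Y.shape[0], X.shape[1]), np.nan)
    resid_var = np.full(Y.shape[0], np.nan)
    dof = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    if valid.any():
        sol, *_ = np.linalg.lstsq(X, Y[valid].T, rcond=None)
        B[valid] = sol.T
        resid = Y[valid] - B[valid] @ X.T
        resid_var[valid] = (resid ** 2).sum(axis=1) / max(dof, 1)
    se = np.sqrt(resid_var[:, None] * np.diag(xtx_inv)[None, :])
    return GLMResult(betas=pd.DataFrame(B, columns=names),
                     se=pd.DataFrame(se, columns=names),
                     resid_var=resid_var, dof=dof, design_matrix=X, names=names)


def _mean_scale_correction(betas: np.ndarray, xbar: np.ndarray,
                           stream: str) -> np.ndarray:
    """Undo the multiplicative bias of run-mean percent-signal-change scaling.

    The run mean itself contains the condition responses, so scaling divides
    every effect by (1 -/+ sum_theta g_theta * xbar_theta / 100).  Solving the
    resulting fixed point gives g = beta / (1 + s * sum beta xbar / 100) with
    s = +1 for the (negated) VASO ratio and s = -1 for the BOLD stream.
    """
    s = 1.0 if stream == "vaso" else -1.0
    denom = 1.0 + s * (betas * xbar[None, :]).sum(axis=1) / 100.0
    return betas / denom[:, None]


def condition_responses(series: LaminarSeries, design: BlockDesign,
                        stream: str = "vaso", drift_order: int = 3,
                        motion: np.ndarray | None = None,
                        mean_scale_correction: bool = True) -> dict:
    """Per-voxel condition response amplitudes (% signal change) for one
    stream of an interleaved session.

    ``stream='vaso'`` runs the full BOLD-correction chain and returns the CBV
    response (positive for activation); ``stream='bold'`` analyses the
    not-nulled stream directly.  Returns a dict with ``betas`` (voxel x
    condition DataFrame), ``se``, and the underlying ``glm`` result.
    """
    nulled, notnulled = split_and_align(series)
    if stream == "vaso":
        src = boco_correct(nulled, notnulled)
        sign = -1.0
    elif stream == "bold":
        src = notnulled
        sign = 1.0
    else:
        raise ValueError("stream must be 'vaso' or 'bold'")
    native = src.native
    y_all = percent_signal_change(src.data[:, native], src.run_index[native])
    times_all = src.times[native]
    runs_all = src.run_index[native]
    cond_names = [f"theta{c}" for c in design.conditions]
    # run-wise GLM: per-run mean scaling makes the scale run-specific, so the
    # closed-form correction is applied per run before averaging across runs
    per_run_betas, per_run_var, glms = [], [], []
    regs_all = condition_regressors(design, times_all)
    for r in np.unique(runs_all):
        sel = runs_all == r
        X, names = build_design_matrix(times_all[sel], design, runs_all[sel],
                                       drift_order,
                                       None if motion is None else motion[sel])
        glm = fit_glm(y_all[:, sel], X, names)
        glms.append(glm)
        betas = sign * glm.betas[cond_names].to_numpy()
        if mean_scale_correction:
            xbar = np.array([regs_all[c][sel].mean() for c in design.conditions])
            betas = _mean_scale_correction(betas, xbar, stream)
        per_run_betas.append(betas)
        per_run_var.append(glm.se[cond_names].to_numpy() ** 2)
    n_runs = len(per_run_betas)
    betas = np.mean(per_run_betas, axis=0)
    se = np.sqrt(np.sum(per_run_var, axis=0)) / n_runs
    out_betas = pd.DataFrame(betas, columns=[str(c) for c in design.conditions])
    out_se = pd.DataFrame(se, columns=out_betas.columns)
    dof = sum(g.dof for g in glms)
    return {"betas": out_betas, "se": out_se, "glms": glms, "dof": dof,
            "stream": stream}
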