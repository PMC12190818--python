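"""Layer-specific generalized psychophysiological interaction (gPPI).

Condition-specific effective connectivity between cortical depths is
estimated without deconvolution: the PPI term for condition theta is the
element-wise product of the seed timecourse with the stimulus boxcar shifted
by one TR (a coarse stand-in for the haemodynamic delay, appropriate when the
seed HRF is uncertain).  The target GLM contains the seed timecourse, the
shifted stimulus boxcars, the three PPI terms, and per-run drift regressors;
saliency-dependent connectivity is the PPI-beta difference between the 90-deg
and 15-deg conditions.

Default pathways mirror the feedforward (V1 superficial -> IPS middle) and
feedback (IPS deep -> V1 deep) hypotheses; an all-layer matrix is available
by enumerating seed/target pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlockDesign
from .preproc import DesignError, fit_glm
from .stats import holm_correct, paired_t

__all__ = ["PPIDesign", "shifted_boxcars", "build_ppi_design", "fit_gppi",
           "saliency_connectivity", "group_pathway_test", "PATHWAYS"]

#: (seed region, seed layer, target region, target layer)
PATHWAYS = {
    "feedforward": ("V1", "superficial", "IPS", "middle"),
    "feedback": ("IPS", "deep", "V1", "deep"),
}


def shifted_boxcars(design: BlockDesign, times: np.ndarray,
                    shift_s: float | None = None) -> dict:
    """Condition boxcars shifted by one TR (default: one pair TR) evaluated
    at the sample times."""
    if shift_s is None:
        shift_s = design.pair_tr
    times = np.asarray(times, dtype=float)
    run_idx = np.searchsorted(
        np.arange(1, design.n_runs) * design.run_duration, times, side="right")
    out = {c: np.zeros_like(times) for c in design.conditions}
    for r, run in enumerate(design.runs):
        sel = run_idx == r
        t_local = times[sel] - r * design.run_duration
        for b in run.blocks:
            on = b.onset + shift_s
            out[b.condition][sel] += ((t_local >= on)
                                      & (t_local < on + b.duration)).astype(float)
    for c in out:
        out[c] = np.clip(out[c], 0.0, 1.0)
    return out


@dataclass
class PPIDesign:
    X: np.ndarray
    names: list
    conditions: list
    times: np.ndarray


def build_ppi_design(seed_series: np.ndarray, design: BlockDesign,
                     times: np.ndarray, shift_s: float | None = None,
                     drift_order: int = 3,
                     motion: np.ndarray | None = None) -> PPIDesign:
    """Assemble the gPPI design matrix for one seed timecourse.

    Columns: seed, one shifted boxcar per condition, one PPI (boxcar * seed)
    term per condition, per-run Legendre drifts, optional motion.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if seed_series.shape != times.shape:
        raise DesignError("seed series and time grid lengths differ")
    boxes = shifted_boxcars(design, times, shift_s)
    cols = [seed_series]
    names = ["seed"]
    for c in design.conditions:
        cols.append(boxes[c])
        names.append(f"box{c}")
    for c in design.conditions:
        cols.append(boxes[c] * seed_series)
        names.append(f"ppi{c}")
    run_idx = np.searchsorted(
        np.arange(1, design.n_runs) * design.run_duration, times, side="right")
    for r in np.unique(run_idx):
        sel = run_idx == r
        x = np.linspace(-1.0, 1.0, int(sel.sum()))
        for k in range(drift_order + 1):
            col = np.zeros_like(times)
            col[sel] = np.polynomial.legendre.Legendre.basis(k)(x)
            cols.append(col)
            names.append(f"run{r}_drift{k}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float).T).T
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion{j}")
    return PPIDesign(X=np.column_stack(cols), names=names,
                     conditions=list(design.conditions), times=times)


def fit_gppi(target_series: np.ndarray, ppi: PPIDesign) -> pd.Series:
    """OLS condition-specific coupling estimates for one target timecourse."""
    glm = fit_glm(np.atleast_2d(target_series), ppi.X, ppi.names)
    return glm.betas.iloc[0]


def saliency_connectivity(betas: pd.Series) -> float:
    """Saliency-dependent connectivity: PPI beta (90 deg) - PPI beta (15 deg)."""
    return float(betas["ppi90"] - betas["ppi15"])


def group_pathway_test(deltas: pd.DataFrame) -> pd.DataFrame:
    """Group inference on pathway x subject connectivity contrasts.

    ``deltas``: subjects x pathways.  Paired t of the two PPI betas across
    subjects reduces to a one-sample t on the per-subject difference; Holm
    correction is applied over the tested pathways.
    """
    rows = []
    for name in deltas.columns:
        d = deltas[name].to_numpy()
        res = paired_t(d, np.zeros_like(d))
        rows.append({"pathway": name, "mean_delta": d.mean(), **res})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_correct(out["p"].to_numpy())
    return out
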