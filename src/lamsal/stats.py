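"""Saliency-sensitive response statistics.

Core quantities
---------------
Given per-subject layer x condition CBV responses r(s, l, theta), the
normalized response divides each subject by their root-mean-square over the
nine layer x condition cells and multiplies by the group mean of those RMS
values, removing between-subject amplitude differences while preserving the
group scale:

    S(s, l, theta) = r(s, l, theta) / r_norm(s) * rbar,
    r_norm(s) = RMS_{l,theta} r(s, l, theta),   rbar = mean_s r_norm(s)

The saliency-sensitive response is the 90-minus-15-degree difference,
SS(s, l) = S(s, l, 90) - S(s, l, 15), which cancels partial-volume background
suppression shared by the two foreground conditions.

Inference: within-subject (repeated-measures) ANOVA with Greenhouse-Geisser
correction when sphericity is violated, paired t-tests with Holm correction,
and Pearson brain-behavior correlations with family-wise error control by
max-statistic permutation across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .laminar import GM_LAYERS

__all__ = ["NormalizedProfile", "normalize_responses",
           "saliency_sensitive_response", "rm_anova_one_way",
           "rm_anova_two_way", "paired_t", "holm_correct",
           "brain_behavior_correlation", "power_rm_anova",
           "strongest_layer"]


@dataclass
class NormalizedProfile:
    s_fmri: np.ndarray      # (n_subjects, n_layers, n_thetas)
    rnorm: np.ndarray       # (n_subjects,)
    rbar: float
    layers: tuple = GM_LAYERS
    thetas: tuple = (90, 15, 0)
    region: str | None = None


def normalize_responses(r: np.ndarray, region: str | None = None,
                        thetas=(90, 15, 0)) -> NormalizedProfile:
    """Normalize a subject x layer x condition response table (see module
    docstring).  Raises for an all-zero subject (undefined normalization)."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 3:
        raise ValueError("expected (subjects, layers, conditions)")
    rnorm = np.sqrt(np.mean(r ** 2, axis=(1, 2)))
    if np.any(rnorm <= 0) or not np.all(np.isfinite(rnorm)):
        raise ValueError("normalization undefined: zero or non-finite subject RMS")
    rbar = float(rnorm.mean())
    s = r / rnorm[:, None, None] * rbar
    return NormalizedProfile(s_fmri=s, rnorm=rnorm, rbar=rbar, thetas=tuple(thetas),
                             region=region)


def saliency_sensitive_response(norm: NormalizedProfile) -> np.ndarray:
    """SS(s, l): normalized 90-deg minus 15-deg response per subject/layer."""
    i90 = norm.thetas.index(90)
    i15 = norm.thetas.index(15)
    return norm.s_fmri[:, :, i90] - norm.s_fmri[:, :, i15]


def strongest_layer(ss: np.ndarray, layers=GM_LAYERS) -> str:
    """Cortical depth with the strongest group-mean saliency-sensitive
    response (the depth used for brain-behavior correlation)."""
    return layers[int(np.argmax(np.asarray(ss).mean(axis=0)))]


# ---------------------------------------------------------------- ANOVA ----

def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum()
                     + k ** 2 * grand ** 2)
    return float(num / den) if den > 0 else 1.0


def _mauchly_p(data: np.ndarray) -> float:
    """Mauchly's sphericity test on the orthonormal contrast covariance."""
    n, k = data.shape
    if k < 3:
        return 1.0
    # orthonormal contrasts via QR of a centering basis
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    S = C.T @ np.cov(data, rowvar=False) @ C
    d = k - 1
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (eig.mean() ** d)
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    dof = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, dof))


def rm_anova_one_way(data: np.ndarray, correction: str = "auto") -> dict:
    """One-way repeated-measures ANOVA on a subject x condition table.

    ``correction``: 'auto' applies the Greenhouse-Geisser adjustment only when
    Mauchly's test rejects sphericity (p < .05); 'always'/'never' force it.
    Returns F, dof, p, p_gg, epsilon, and the p-value actually selected.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    eps = _gg_epsilon(y)
    p = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
    mauchly = _mauchly_p(y)
    if correction == "always" or (correction == "auto" and mauchly < 0.05):
        p_sel = p_gg
    else:
        p_sel = p
    return {"F": float(F), "df1": df1, "df2": df2, "p": p, "p_gg": p_gg,
            "epsilon": float(eps), "mauchly_p": mauchly, "p_selected": p_sel}


def rm_anova_two_way(data: np.ndarray, factor_a: str = "depth",
                     factor_b: str = "theta", levels_a=None, levels_b=None,
                     correction: str = "auto") -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on a (subject, A, B) array.

    Backed by pingouin's repeated-measures ANOVA; sphericity-corrected
    p-values are selected per effect following the Mauchly-gated convention
    of ``rm_anova_one_way``.
    """
    import pingouin as pg

    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected (subjects, levels_a, levels_b)")
    if np.isnan(y).any():
        raise ValueError("missing cells: the design must be complete")
    n, ka, kb = y.shape
    if n < 3:
        raise ValueError("need >= 3 subjects")
    levels_a = list(levels_a) if levels_a is not None else list(range(ka))
    levels_b = list(levels_b) if levels_b is not None else list(range(kb))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), ka * kb),
        factor_a: np.tile(np.repeat(np.arange(ka), kb), n),
        factor_b: np.tile(np.arange(kb), n * ka),
        "y": y.ravel(),
    })
    long[factor_a] = long[factor_a].map(dict(enumerate(levels_a)))
    long[factor_b] = long[factor_b].map(dict(enumerate(levels_b)))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        table = pg.rm_anova(data=long, dv="y", within=[factor_a, factor_b],
                            subject="subject", correction=True, detailed=True)
    table = table.rename(columns={"p-unc": "p_unc", "p-GG-corr": "p_GG_corr"})
    # collapse the marginal table per effect for sphericity gating
    sel = []
    for _, row in table.iterrows():
        eff = row["Source"]
        if "*" in eff:
            cells = y.reshape(n, ka * kb)
        elif eff == factor_a:
            cells = y.mean(axis=2)
        else:
            cells = y.mean(axis=1)
        mauchly = _mauchly_p(cells)
        use_gg = correction == "always" or (correction == "auto" and mauchly < 0.05)
        p_gg = row.get("p_GG_corr", np.nan)
        p_unc = row["p_unc"]
        sel.append(p_gg if (use_gg and np.isfinite(p_gg)) else p_unc)
    table["p_selected"] = sel
    return table


def paired_t(x, y) -> dict:
    """Paired t-test; raises on zero-variance differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return {"t": 0.0, "dof": x.size - 1, "p": 1.0}
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(x, y)
    return {"t": float(t), "dof": x.size - 1, "p": float(p)}


def holm_correct(pvals) -> np.ndarray:
    """Holm step-down family-wise error adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="holm")[1]


# -------------------------------------------------- permutation FWE --------

def brain_behavior_correlation(ss_fmri: pd.DataFrame | np.ndarray,
                               ss_behavior: np.ndarray, n_perm: int = 10000,
                               seed: int | np.random.Generator | None = 0,
                               two_sided: bool = False) -> pd.DataFrame:
    """Per-ROI Pearson correlation with max-statistic permutation FWE.

    ``ss_fmri``: subjects x ROIs saliency-sensitive responses (at each ROI's
    strongest depth); ``ss_behavior``: per-subject behavioral sensitivity to
    saliency.  The permutation shuffles the subject correspondence between
    the two measures; the null is the distribution of the maximum r (signed
    by default, |r| if ``two_sided``) across ROIs, giving the family-wise
    corrected p-value and the FWE threshold (95th percentile of the null).
    """
    X = ss_fmri.to_numpy() if isinstance(ss_fmri, pd.DataFrame) else np.asarray(ss_fmri)
    X = X.astype(float)
    names = (list(ss_fmri.columns) if isinstance(ss_fmri, pd.DataFrame)
             else [f"roi{j}" for j in range(X.shape[1])])
    yv = np.asarray(ss_behavior, dtype=float)
    n = yv.size
    if n < 5:
        raise ValueError("need >= 5 subjects")
    if X.shape[0] != n:
        raise ValueError("subject mismatch between fMRI and behavior")
    if np.any(X.std(axis=0) == 0) or yv.std() == 0:
        raise ValueError("constant input: correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Zx = (X - X.mean(axis=0)) / X.std(axis=0)
    zy = (yv - yv.mean()) / yv.std()
    r_obs = Zx.T @ zy / n
    perm = rng.permuted(np.tile(zy, (n_perm, 1)), axis=1)
    R = perm @ Zx / n                                   # (n_perm, n_roi)
    stat = np.abs(R) if two_sided else R
    obs = np.abs(r_obs) if two_sided else r_obs
    max_null = stat.max(axis=1)
    p_raw = (1 + (stat >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    p_fwe = (1 + (max_null[:, None] >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    thresh = float(np.quantile(max_null, 0.95))
    return pd.DataFrame({"roi": names, "r": r_obs, "p_raw": p_raw,
                         "p_fwe": p_fwe, "fwe_threshold": thresh})


# ------------------------------------------------------- power -------------

def power_rm_anova(n_subjects: int = 20, n_conditions: int = 3,
                   effect_f: float = 0.4, rho: float = 0.5,
                   n_sims: int = 5000, alpha: float = 0.05,
                   seed: int | np.random.Generator | None = 0) -> float:
    """Monte-Carlo power of a one-way within-subjects ANOVA.

    Condition means are spaced so that Cohen's f (SD of condition means over
    the total score SD) equals ``effect_f``; scores follow a compound-
    symmetric model with correlation ``rho`` between repeated measures and
    unit total variance.  Returns the rejection rate at ``alpha``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = n_subjects, n_conditions
    m = np.linspace(-1.0, 1.0, n_conditions)
    m *= effect_f / np.sqrt(np.mean(m ** 2))            # SD of means = f (total SD 1)
    n_rej = 0
    subj_sd = np.sqrt(rho)
    err_sd = np.sqrt(1.0 - rho)
    for _ in range(n_sims):
        y = (m[None, :] + subj_sd * rng.normal(size=(n_subjects, 1))
             + err_sd * rng.normal(size=k))
        res = rm_anova_one_way(y, correction="auto")
        n_rej += res["p_selected"] < alpha
    return n_rej / n_sims
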