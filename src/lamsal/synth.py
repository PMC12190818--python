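"""Ground-truth-known synthetic laminar VASO/BOLD data.

This module is the generative counterpart of the analysis chain: it encodes
the three laminar-origin hypotheses for visual saliency signals as scenario
gain tables (which cortical depth of which region responds how strongly to
each orientation-contrast condition), builds a parametric cortical patch with
partial-volume layer weights and pRF-carrying vertices, and simulates the
interleaved blood-nulled / not-nulled acquisition, including BOLD (T2*)
contamination of the nulled frames, slow scanner drift, and Gaussian noise.

Scenarios
---------
``feedback_parietal``
    saliency computed in parietal cortex, reaching V1 by feedback: strongest
    in deep (and superficial) V1 and in deep IPS.
``v1sh``
    V1 saliency hypothesis: saliency emerges via horizontal connections in
    superficial V1 and feeds forward into middle IPS.
``sc_tectothalamic``
    saliency generated in the superior colliculus, reaching cortex through
    the tecto-thalamo-cortical route: middle/superficial layers everywhere.

Signal model (per voxel, % of baseline)
---------------------------------------
nulled(t)     = V0 * (1 - sum_theta g_theta x_theta(t)/100) * B~(t) * d_n(t) + noise
notnulled(t)  = V0 * B(t) * d_nn(t) + noise
B(t)          = 1 + sum_theta b_theta x_theta(t)/100,  b = bold_ratio * g

where x_theta is the unit-plateau HRF-convolved block regressor and B~ is the
not-nulled BOLD factor resampled to the nulled frame times with the same
stencil the analysis uses, so the nulled/not-nulled division cancels the
contamination exactly at the acquired timepoints (see docs/methods.md).
The BOLD response is ``bold_ratio`` times the CBV gain; with full
multiplicative contamination the raw nulled signal decreases during
activation only for bold_ratio < 1, hence the default.  VASO sign convention:
activation *decreases* the nulled signal; the analysis reports the negated
percent change as a positive CBV response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BlockDesign, THETAS, condition_regressors
from .laminar import COMPARTMENTS, GM_LAYERS, equivolume_boundaries
from .resample import fill_alternate

__all__ = ["ScenarioSpec", "ColumnModel", "LaminarSeries", "SCENARIOS",
           "REGIONS", "FOREGROUND_ECC", "foreground_center",
           "build_column_model", "simulate_vaso_session", "simulate_gaze",
           "simulate_connectivity_pair"]

REGIONS = ("V1", "V2", "IPS")
SCENARIOS = ("feedback_parietal", "v1sh", "sc_tectothalamic")

#: eccentricity of the foreground bar patch (degrees of visual angle)
FOREGROUND_ECC = 4.3

# per-scenario 90-deg gains, (deep, middle, superficial) % signal change;
# the 15-deg condition scales these by 0.4 and the 0-deg condition is a flat
# 0.25% (texture onset without a salient foreground)
_GAINS_90 = {
    "v1sh": {"V1": (0.3, 0.4, 1.0), "V2": (0.3, 0.7, 0.9), "IPS": (0.3, 1.0, 0.4)},
    "feedback_parietal": {"V1": (1.0, 0.3, 0.8), "V2": (1.0, 0.3, 0.8),
                          "IPS": (1.0, 0.3, 0.3)},
    "sc_tectothalamic": {"V1": (0.3, 1.0, 0.8), "V2": (0.3, 1.0, 0.8),
                         "IPS": (0.3, 1.0, 0.8)},
}
_THETA15_SCALE = 0.4
_THETA0_FLAT = 0.25


def foreground_center(side: str = "right") -> tuple[float, float]:
    """Center of the foreground patch at 4.3 deg eccentricity in the lower
    visual field, on the 45-deg diagonal."""
    x = FOREGROUND_ECC / np.sqrt(2.0)
    return (x if side == "right" else -x, -x)


@dataclass
class ScenarioSpec:
    """Laminar condition-gain table plus noise model for one generative scenario.

    ``gains[region][theta]`` is a (deep, middle, superficial) array in percent
    signal change for the CBV channel; the not-nulled (BOLD) channel responds
    with ``bold_ratio`` times the CBV gain.
    """

    name: str
    gains: dict = field(default_factory=dict)
    noise_sd: float = 0.5       # % signal change per frame
    drift_amp: float = 0.5      # % amplitude scale of Legendre drifts
    bold_ratio: float = 0.7     # BOLD response per unit CBV gain (see methods)
    superficial_bias: float = 0.0   # draining-vein slope for the BOLD channel

    @classmethod
    def default(cls, name: str, **kwargs) -> "ScenarioSpec":
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
        gains = {}
        for region in REGIONS:
            g90 = np.asarray(_GAINS_90[name][region], dtype=float)
            gains[region] = {90: g90, 15: _THETA15_SCALE * g90,
                             0: np.full(3, _THETA0_FLAT)}
        return cls(name=name, gains=gains, **kwargs)

    def gain(self, region: str, layer: str, theta: int) -> float:
        return float(self.gains[region][theta][GM_LAYERS.index(layer)])

    def validate(self) -> None:
        for region, per_theta in self.gains.items():
            for theta, g in per_theta.items():
                g = np.asarray(g, dtype=float)
                if not np.all(np.isfinite(g)) or np.any(g < 0):
                    raise ValueError(f"gains must be finite and >= 0 "
                                     f"({region}, theta={theta})")
        if self.name == "v1sh":
            assert self.gain("V1", "superficial", 90) > self.gain("V1", "deep", 90)
            assert self.gain("IPS", "middle", 90) > self.gain("IPS", "deep", 90)
        if self.name == "feedback_parietal":
            ips = self.gains["IPS"][90]
            assert np.argmax(ips) == 0, "IPS deep gain must be maximal"

    def zeroed(self) -> "ScenarioSpec":
        """Copy with all condition gains set to zero (null scenario).

        The copy is renamed so the laminar-ordering invariants of the named
        scenarios no longer apply to it.
        """
        gains = {r: {t: np.zeros(3) for t in per} for r, per in self.gains.items()}
        return ScenarioSpec(f"{self.name}_null", gains, self.noise_sd,
                            self.drift_amp, self.bold_ratio, self.superficial_bias)


@dataclass
class ColumnModel:
    """Parametric cortical-column model.

    ``voxels``: region label, grid index, center radius, and partial-volume
    weights over (wm, csf, deep, middle, superficial) per voxel.
    ``vertices``: surface nodes with a cortical depth fraction (0 = WM
    boundary, 1 = pial) and an isotropic Gaussian pRF (x0, y0, sigma in deg).
    """

    voxels: pd.DataFrame
    vertices: pd.DataFrame
    wm_radius: float
    pial_radius: float

    @property
    def weight_columns(self):
        return [f"w_{c}" for c in COMPARTMENTS]

    def weights(self, region: str | None = None) -> np.ndarray:
        df = self.voxels if region is None else self.voxels[self.voxels.region == region]
        return df[self.weight_columns].to_numpy()

    def region_mask(self, region: str) -> np.ndarray:
        return (self.voxels.region == region).to_numpy()

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _wedge_voxels(region: str, n_voxels: int, wm_radius: float,
                  pial_radius: float, voxel_size: float, geometry: str,
                  subsample: int = 16) -> pd.DataFrame:
    """Square voxel grid intersected with an annular wedge; partial-volume
    weights by sub-voxel area sampling against the equi-volume boundaries."""
    b = equivolume_boundaries(wm_radius, pial_radius, (1 / 3, 2 / 3), geometry)
    edges = np.array([wm_radius, b[0], b[1], pial_radius])
    half_span = np.deg2rad(30.0)   # 60-deg wedge about the x axis
    margin = 1.5 * voxel_size
    r_lo, r_hi = wm_radius - margin, pial_radius + margin
    # voxel centers on a grid covering the wedge bounding box
    xs = np.arange(r_lo * np.cos(half_span) - voxel_size, r_hi + voxel_size,
                   voxel_size)
    ys = np.arange(-r_hi * np.sin(half_span) - voxel_size,
                   r_hi * np.sin(half_span) + voxel_size, voxel_size)
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    ox, oy = np.meshgrid(offs, offs)
    rows = []
    for iy, yc in enumerate(ys):
        for ix, xc in enumerate(xs):
            r_c = np.hypot(xc, yc)
            if not (r_lo <= r_c <= r_hi):
                continue
            if abs(np.arctan2(yc, xc)) > half_span:
                continue
            rr = np.hypot(xc + ox * voxel_size, yc + oy * voxel_size).ravel()
            w = np.empty(5)
            w[0] = np.mean(rr < edges[0])                      # wm
            w[1] = np.mean(rr >= edges[3])                     # csf
            for j in range(3):                                 # deep/mid/sup
                w[2 + j] = np.mean((rr >= edges[j]) & (rr < edges[j + 1]))
            rows.append({"region": region, "ix": ix, "iy": iy,
                         "x": xc, "y": yc, "radius": r_c,
                         **{f"w_{c}": w[k] for k, c in enumerate(COMPARTMENTS)}})
    df = pd.DataFrame(rows)
    gm = df[df[[f"w_{c}" for c in GM_LAYERS]].sum(axis=1) > 0.2]
    if len(gm) < n_voxels:
        raise ValueError("voxel grid too coarse for requested voxel count; "
                         "decrease voxel_size")
    # evenly spaced in radius so every depth is represented
    gm = gm.sort_values("radius", kind="stable")
    take = np.unique(np.round(np.linspace(0, len(gm) - 1, n_voxels)).astype(int))
    i = 0
    while len(take) < n_voxels:   # fill duplicates from unused indices
        if i not in take:
            take = np.sort(np.append(take, i))
        i += 1
    return gm.iloc[take].reset_index(drop=True)


def build_column_model(n_voxels_per_region: int = 24, wm_radius: float = 10.0,
                       pial_radius: float = 12.5, voxel_size: float | None = None,
                       geometry: str = "annulus2d",
                       n_vertices_per_region: int = 60,
                       prf_scatter: float = 0.8, prf_sigma: float = 1.0,
                       seed: int | None = 0) -> ColumnModel:
    """Build the parametric column model for regions V1, V2 and IPS.

    Each region is an annular wedge of cortex between ``wm_radius`` and
    ``pial_radius`` (arbitrary length units; thickness/radius ratio sets the
    curvature), cut by a square voxel grid; voxel layer weights are volume
    fractions over WM/CSF/deep/middle/superficial.  Vertices carry equally
    many nodes per depth third, with pRF centers scattered around the two
    foreground locations in the lower visual field.
    """
    if n_voxels_per_region < 3:
        raise ValueError("need at least 3 voxels per region")
    if pial_radius <= wm_radius:
        raise ValueError("degenerate geometry: pial radius must exceed WM radius")
    if voxel_size is None:
        voxel_size = (pial_radius - wm_radius) / 6.0
    rng = np.random.default_rng(seed)
    vox_frames, vert_frames = [], []
    for region in REGIONS:
        vox = _wedge_voxels(region, n_voxels_per_region, wm_radius, pial_radius,
                            voxel_size, geometry)
        gm_w = vox[[f"w_{c}" for c in GM_LAYERS]].to_numpy()
        dominant = set(np.argmax(gm_w, axis=1)[gm_w.max(axis=1) > 0.5])
        if dominant != {0, 1, 2}:
            raise ValueError(f"{region}: not all layers have a dominated voxel; "
                             "increase n_voxels_per_region or refine the grid")
        vox_frames.append(vox)
        depth = ((np.arange(n_vertices_per_region) % 3) + 0.5) / 3.0
        side = np.where(np.arange(n_vertices_per_region) % 2 == 0, "right", "left")
        centers = np.array([foreground_center(s) for s in side])
        centers += rng.normal(0.0, prf_scatter, size=centers.shape)
        vert_frames.append(pd.DataFrame({
            "region": region, "depth": depth,
            "x0": centers[:, 0], "y0": centers[:, 1],
            "sigma": prf_sigma * rng.uniform(0.75, 1.5, n_vertices_per_region),
        }))
    return ColumnModel(voxels=pd.concat(vox_frames, ignore_index=True),
                       vertices=pd.concat(vert_frames, ignore_index=True),
                       wm_radius=wm_radius, pial_radius=pial_radius)


@dataclass
class LaminarSeries:
    """Voxel x time matrix with alternating nulled/not-nulled frame labels."""

    data: np.ndarray            # (n_voxels, n_frames), arbitrary signal units
    frame_labels: np.ndarray    # 'nulled' / 'notnulled'
    frame_times: np.ndarray     # s
    meta: dict

    def __post_init__(self):
        if (self.frame_labels == "nulled").sum() != (self.frame_labels == "notnulled").sum():
            raise ValueError("unequal counts of nulled and not-nulled frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data,
                          columns=[f"t{j}" for j in range(self.data.shape[1])])
        return df


def simulate_vaso_session(model: ColumnModel, design: BlockDesign,
                          scenario: ScenarioSpec,
                          seed: int | np.random.Generator | None = 0,
                          baseline: float = 100.0) -> LaminarSeries:
    """Simulate one interleaved nulled/not-nulled session.

    Activation decreases the nulled signal (VASO sign convention) by the
    scenario gain mixed through the voxel layer weights; not-nulled frames
    carry a BOLD-like positive response of ``bold_ratio`` times the CBV gain,
    which also contaminates the nulled frames multiplicatively (see module
    docstring).  Additive Gaussian noise and per-run Legendre drifts complete
    the noise model.  Deterministic given the seed.
    """
    scenario.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = design.frame_times()
    labels = design.frame_labels()
    run_idx = design.run_index()
    n_frames = times.size
    nulled_ix = np.flatnonzero(labels == "nulled")
    notnulled_ix = np.flatnonzero(labels == "notnulled")

    regs = condition_regressors(design)
    thetas = [c for c in design.conditions]
    X = np.stack([regs[c] for c in thetas])          # (n_theta, n_frames)

    # per-voxel CBV and BOLD gains mixed through layer weights (WM/CSF -> 0)
    gm_cols = [f"w_{c}" for c in GM_LAYERS]
    W = model.voxels[gm_cols].to_numpy()             # (n_vox, 3)
    g_cbv = np.zeros((model.n_voxels, len(thetas)))
    for region in model.voxels.region.unique():
        mask = model.region_mask(region)
        G = np.stack([np.asarray(scenario.gains[region][t], dtype=float)
                      for t in thetas], axis=1)       # (3 layers, n_theta)
        g_cbv[mask] = W[mask] @ G
    bias = 1.0
    if scenario.superficial_bias:
        # draining-vein amplification of the BOLD channel toward the surface
        depth = (model.voxels["radius"].to_numpy() - model.wm_radius) / (
            model.pial_radius - model.wm_radius)
        bias = 1.0 + scenario.superficial_bias * np.clip(depth, 0, 1)[:, None]
    g_bold = scenario.bold_ratio * g_cbv * bias

    vaso_resp = (g_cbv / 100.0) @ X                  # (n_vox, n_frames)
    bold_factor = 1.0 + (g_bold / 100.0) @ X
    # contamination of nulled frames: the not-nulled BOLD factor resampled to
    # the nulled frame times with the same operator the analysis uses, so
    # the BOLD-correction division cancels it exactly
    nn_mask = labels == "notnulled"
    bold_full = fill_alternate(np.where(nn_mask, bold_factor, np.nan),
                               nn_mask, run_idx)

    data = np.empty((model.n_voxels, n_frames))
    data[:, nulled_ix] = (baseline * (1.0 - vaso_resp[:, nulled_ix])
                          * bold_full[:, nulled_ix])
    data[:, notnulled_ix] = baseline * bold_factor[:, notnulled_ix]

    if scenario.drift_amp > 0:
        for r in range(design.n_runs):
            for ix in (nulled_ix, notnulled_ix):
                sel = ix[run_idx[ix] == r]
                x = np.linspace(-1.0, 1.0, sel.size)
                basis = np.stack([np.polynomial.legendre.Legendre.basis(k)(x)
                                  for k in (1, 2, 3)])       # (3, n)
                coef = rng.normal(0.0, scenario.drift_amp,
                                  size=(model.n_voxels, 3))
                data[:, sel] += baseline / 100.0 * coef @ basis
    if scenario.noise_sd > 0:
        data += baseline / 100.0 * rng.normal(0.0, scenario.noise_sd, data.shape)

    return LaminarSeries(data=data, frame_labels=labels, frame_times=times,
                         meta={"pair_tr": design.pair_tr,
                               "frame_interval": design.frame_interval,
                               "n_runs": design.n_runs,
                               "frames_per_run": design.frames_per_run,
                               "baseline": baseline,
                               "conditions": thetas,
                               "scenario": scenario.name})


def simulate_gaze(n_samples: int, sd_x: float = 0.3, sd_y: float = 0.3,
                  rho: float = 0.0, blink_rate: float = 0.1,
                  seed: int | np.random.Generator | None = 0,
                  fs: float = 1000.0, center=(0.0, 0.0),
                  blink_ms=(100.0, 300.0)) -> pd.DataFrame:
    """Bivariate-Gaussian fixation scatter sampled at ``fs`` Hz with blink gaps.

    Blinks arrive as a Poisson process (``blink_rate`` per second) with
    uniform durations; samples inside a blink are flagged invalid and set to
    NaN.  Columns: time (ms), x, y (deg), valid, block.
    """
    if sd_x < 0 or sd_y < 0:
        raise ValueError("standard deviations must be >= 0")
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.array([[sd_x ** 2, rho * sd_x * sd_y],
                    [rho * sd_x * sd_y, sd_y ** 2]])
    xy = rng.multivariate_normal(center, cov, size=n_samples, method="eigh")
    t_ms = np.arange(n_samples) / fs * 1000.0
    valid = np.ones(n_samples, dtype=bool)
    if blink_rate > 0:
        t = rng.exponential(1.0 / blink_rate)
        while t * fs < n_samples:
            dur = rng.uniform(*blink_ms) / 1000.0
            i0, i1 = int(t * fs), min(n_samples, int((t + dur) * fs))
            valid[i0:i1] = False
            t += dur + rng.exponential(1.0 / blink_rate)
    xy[~valid] = np.nan
    return pd.DataFrame({"time": t_ms, "x": xy[:, 0], "y": xy[:, 1],
                         "valid": valid, "block": 0})


def simulate_connectivity_pair(design: BlockDesign, coupling: dict,
                               seed_gain: float = 1.0, target_direct: float = 0.5,
                               target_seed_weight: float = 0.3,
                               noise_sd: float = 0.5, shift_s: float | None = None,
                               seed: int | np.random.Generator | None = 0):
    """Seed/target ROI-mean BOLD series with condition-specific coupling.

    target = direct response + target_seed_weight * seed
             + sum_theta coupling[theta] * (shifted boxcar_theta * seed) + noise

    mirrors the generalized-PPI generative model at the timeseries level, on
    the not-nulled (BOLD) frame grid.  Returns ``(times, seed_series,
    target_series)`` in percent-signal-change units.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = design.frame_times()[1::2]               # not-nulled frames
    regs = condition_regressors(design, times)
    if shift_s is None:
        shift_s = design.pair_tr
    from .connectivity import shifted_boxcars
    boxes = shifted_boxcars(design, times, shift_s)
    seed_series = seed_gain * sum(regs.values())
    seed_series = seed_series + rng.normal(0.0, noise_sd, times.size)
    target = (target_direct * sum(regs.values())
              + target_seed_weight * seed_series)
    for theta, c in coupling.items():
        target = target + c * boxes[theta] * seed_series
    target = target + rng.normal(0.0, noise_sd, times.size)
    return times, seed_series, target
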