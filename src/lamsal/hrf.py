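"""Canonical haemodynamic response and block regressors.

A single HRF implementation is shared by the forward simulator and the GLM so
that estimated condition amplitudes are directly comparable with generative
gains (no model mismatch between synthesis and analysis).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["double_gamma_hrf", "block_response", "sample_block_regressor"]

#: fine time step (s) used internally for convolution
DT = 0.1


def double_gamma_hrf(t: np.ndarray, peak: float = 5.0, undershoot: float = 15.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Double-gamma HRF with unit-scale gamma densities.

    Parameters
    ----------
    t : array of times in seconds (values < 0 give 0)
    peak : time-to-peak of the positive lobe (s)
    undershoot : time-to-peak of the negative lobe (s)
    ratio : peak-to-undershoot amplitude ratio
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # gamma density with shape a, scale 1 peaks at a-1  ->  a = peak + 1
    for a, w in ((peak + 1.0, 1.0), (undershoot + 1.0, -1.0 / ratio)):
        logpdf = (a - 1.0) * np.log(tp) - tp - gammaln(a)
        h[pos] += w * np.exp(logpdf)
    return h


def block_response(onsets, duration: float, t_max: float,
                   dt: float = DT) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved boxcar on a fine grid, normalized to unit plateau.

    The response of a single block is scaled so its maximum is exactly 1; a
    condition simulated with gain ``g`` therefore produces a peak response of
    ``g`` percent signal change.

    Returns ``(t_fine, response)``.
    """
    n = int(np.ceil(t_max / dt)) + 1
    t_fine = np.arange(n) * dt
    box = np.zeros(n)
    for on in np.atleast_1d(onsets):
        i0 = int(round(on / dt))
        i1 = min(n, int(round((on + duration) / dt)))
        if i0 < n:
            box[max(i0, 0):i1] = 1.0
    hrf_t = np.arange(0.0, 40.0, dt)
    h = double_gamma_hrf(hrf_t)
    resp = np.convolve(box, h)[:n] * dt
    # unit-plateau normalization from a single isolated block
    ref_n = int(round((duration + 40.0) / dt))
    ref_box = np.zeros(ref_n)
    ref_box[: int(round(duration / dt))] = 1.0
    ref = np.convolve(ref_box, h)[:ref_n] * dt
    resp /= ref.max()
    return t_fine, resp


def sample_block_regressor(times: np.ndarray, onsets, duration: float,
                           dt: float = DT) -> np.ndarray:
    """Evaluate the unit-plateau block response at arbitrary sample times."""
    times = np.asarray(times, dtype=float)
    t_max = float(times.max()) + dt
    t_fine, resp = block_response(onsets, duration, t_max, dt=dt)
    return np.interp(times, t_fine, resp)
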