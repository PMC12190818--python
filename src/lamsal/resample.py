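"""Temporal resampling of one interleaved stream onto the full frame grid.

The interleaved acquisition leaves each stream with samples at every other
frame time; the missing alternate points sit exactly midway between two
samples.  They are filled with a 4-point cubic-Lagrange midpoint stencil
(-1/16, 9/16, 9/16, -1/16) — exact for cubic polynomials — falling back to
the linear midpoint where only two neighbours exist and to edge-hold at run
boundaries.  Runs are resampled independently (no interpolation across run
breaks).

The synthetic generator uses the very same operator to model the T2*
contamination of the nulled frames, so the BOLD-correction division cancels
the contamination exactly at the acquired timepoints.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fill_alternate"]

_W = np.array([-1.0, 9.0, 9.0, -1.0]) / 16.0


def fill_alternate(values: np.ndarray, have: np.ndarray,
                   run_index: np.ndarray) -> np.ndarray:
    """Fill the missing alternate columns of a (voxels x frames) stream.

    ``values`` holds valid data only where ``have`` is True; the returned
    array is complete on the full grid.
    """
    values = np.atleast_2d(values)
    out = np.empty_like(values, dtype=float)
    for r in np.unique(run_index):
        cols = np.flatnonzero(run_index == r)
        h = np.asarray(have)[cols]
        src = values[:, cols[h]]
        pos = np.flatnonzero(h)
        dst = np.empty((values.shape[0], cols.size))
        dst[:, h] = src
        n = src.shape[1]
        for j in np.flatnonzero(~h):
            k = np.searchsorted(pos, j)   # missing point lies between k-1, k
            if k == 0:
                dst[:, j] = src[:, 0]
            elif k == n:
                dst[:, j] = src[:, -1]
            elif 2 <= k <= n - 2:
                dst[:, j] = src[:, k - 2:k + 2] @ _W
            else:
                dst[:, j] = 0.5 * (src[:, k - 1] + src[:, k])
        out[:, cols] = dst
    return out
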