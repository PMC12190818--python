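"""Block-design bookkeeping for the interleaved VASO acquisition.

The acquisition alternates blood-nulled and not-nulled 3D-EPI volumes within a
paired repetition time (pair TR) of 5.02 s, i.e. one frame every 2.51 s.  A run
is a sequence of 30-s stimulus blocks (orientation contrast theta = 90, 15 or
0 deg, two blocks each) preceded by 15-s fixation periods, 270 s in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Block", "RunDesign", "BlockDesign", "make_block_design",
           "condition_regressors", "THETAS", "PAIR_TR", "BLOCK_S", "FIX_S",
           "RUN_S"]

THETAS = (90, 15, 0)
PAIR_TR = 5.02      # s, nulled + not-nulled pair
BLOCK_S = 30.0
FIX_S = 15.0
RUN_S = 270.0


@dataclass(frozen=True)
class Block:
    condition: int | str   # theta in degrees, or a localizer side label
    onset: float           # s from run start, snapped to the frame grid
    duration: float = BLOCK_S


@dataclass
class RunDesign:
    blocks: list[Block]

    def onsets(self, condition) -> np.ndarray:
        return np.array([b.onset for b in self.blocks if b.condition == condition])

    @property
    def conditions(self) -> list:
        seen = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen


@dataclass
class BlockDesign:
    """Multi-run block design on the alternating frame grid."""

    runs: list[RunDesign]
    pair_tr: float = PAIR_TR
    n_pairs: int = int(round(RUN_S / PAIR_TR))   # 54 pairs -> 108 frames/run
    condition_order: tuple | None = None   # canonical order; default: appearance

    def __post_init__(self):
        for run in self.runs:
            blocks = sorted(run.blocks, key=lambda b: b.onset)
            for a, b in zip(blocks, blocks[1:]):
                if a.onset + a.duration > b.onset + 1e-9:
                    raise ValueError("overlapping blocks in run design")

    @property
    def frame_interval(self) -> float:
        return self.pair_tr / 2.0

    @property
    def frames_per_run(self) -> int:
        return 2 * self.n_pairs

    @property
    def run_duration(self) -> float:
        return self.n_pairs * self.pair_tr

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def frame_times(self) -> np.ndarray:
        """Times of all frames, concatenated across runs (run-relative offsets
        of ``run_duration`` keep the global grid uniform)."""
        one = np.arange(self.frames_per_run) * self.frame_interval
        return np.concatenate([one + r * self.run_duration
                               for r in range(self.n_runs)])

    def run_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_runs), self.frames_per_run)

    def frame_labels(self) -> np.ndarray:
        """Alternating 'nulled' / 'notnulled' labels (nulled acquired first)."""
        one = np.where(np.arange(self.frames_per_run) % 2 == 0,
                       "nulled", "notnulled")
        return np.tile(one, self.n_runs)

    @property
    def conditions(self) -> list:
        if self.condition_order is not None:
            return list(self.condition_order)
        seen = []
        for run in self.runs:
            for c in run.conditions:
                if c not in seen:
                    seen.append(c)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = [{"run": r, "condition": b.condition, "onset": b.onset,
                 "duration": b.duration}
                for r, run in enumerate(self.runs) for b in run.blocks]
        return pd.DataFrame(rows)


def condition_regressors(design: BlockDesign, times: np.ndarray | None = None
                         ) -> dict:
    """Unit-plateau HRF-convolved regressor per condition at the given times.

    Shared by the forward simulator and the GLM, so estimated betas are on
    the generative-gain scale (no synthesis/analysis model mismatch).
    """
    from . import hrf
    if times is None:
        times = design.frame_times()
    times = np.asarray(times, dtype=float)
    run_idx = np.searchsorted(
        np.arange(1, design.n_runs) * design.run_duration, times, side="right")
    out = {c: np.zeros_like(times, dtype=float) for c in design.conditions}
    for r, run in enumerate(design.runs):
        sel = run_idx == r
        if not sel.any():
            continue
        t_local = times[sel] - r * design.run_duration
        for cond in design.conditions:
            onsets = run.onsets(cond)
            if len(onsets):
                dur = next(b.duration for b in run.blocks if b.condition == cond)
                out[cond][sel] = hrf.sample_block_regressor(t_local, onsets, dur)
    return out


def _snap(onset: float, frame_interval: float) -> float:
    return round(onset / frame_interval) * frame_interval


def make_block_design(n_runs: int = 2, conditions=THETAS,
                      blocks_per_condition: int = 2, block_s: float = BLOCK_S,
                      fix_s: float = FIX_S, pair_tr: float = PAIR_TR,
                      rng: np.random.Generator | None = None) -> BlockDesign:
    """Counterbalanced block design: each run holds ``blocks_per_condition``
    blocks per condition, each preceded by a fixation period, with onsets
    snapped to the nearest frame time.

    With no ``rng`` the condition order cycles deterministically; with an rng
    the order is permuted independently per run.
    """
    frame_interval = pair_tr / 2.0
    order_base = list(conditions) * blocks_per_condition
    runs = []
    for r in range(n_runs):
        if rng is None:
            order = order_base[r % len(order_base):] + order_base[:r % len(order_base)]
        else:
            order = [order_base[i] for i in rng.permutation(len(order_base))]
        blocks, t = [], 0.0
        for cond in order:
            t += fix_s
            blocks.append(Block(cond, _snap(t, frame_interval), block_s))
            t += block_s
        runs.append(RunDesign(blocks))
    n_pairs = int(round((fix_s + block_s) * len(order_base) / pair_tr))
    return BlockDesign(runs, pair_tr=pair_tr, n_pairs=n_pairs,
                       condition_order=tuple(conditions))
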