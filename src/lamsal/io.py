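"""Readers and writers for the portable on-disk formats.

Timeseries travel either as 4D NIfTI volumes (voxels unfolded along the
first axis, frames along the fourth) with a JSON sidecar for frame labels and
timing, or as a plain voxel x time CSV; designs, gain tables, and trial
tables are CSV; scenario specifications are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import Block, BlockDesign, RunDesign
from .synth import LaminarSeries, ScenarioSpec

__all__ = ["write_series_nifti", "read_series_nifti", "write_series_csv",
           "read_series_csv", "write_design_csv", "read_design_csv",
           "write_scenario_yaml", "read_scenario_yaml"]


def write_series_nifti(series: LaminarSeries, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(series.data[:, None, None, :].astype(np.float32),
                          affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.meta.get("frame_interval", 1.0)))
    nib.save(img, path)
    sidecar = {"frame_labels": series.frame_labels.tolist(),
               "frame_times": np.asarray(series.frame_times).tolist(),
               "meta": {k: v for k, v in series.meta.items()
                        if isinstance(v, (int, float, str, list))}}
    with open(path.with_suffix("").with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_series_nifti(path) -> LaminarSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)[:, 0, 0, :]
    with open(path.with_suffix("").with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return LaminarSeries(data=data,
                         frame_labels=np.asarray(sidecar["frame_labels"]),
                         frame_times=np.asarray(sidecar["frame_times"]),
                         meta=sidecar["meta"])


def write_series_csv(series: LaminarSeries, path) -> None:
    df = pd.DataFrame(series.data.T)
    df.insert(0, "time", series.frame_times)
    df.insert(1, "label", series.frame_labels)
    df.to_csv(path, index=False)


def read_series_csv(path, meta: dict | None = None) -> LaminarSeries:
    df = pd.read_csv(path)
    return LaminarSeries(data=df.drop(columns=["time", "label"]).to_numpy().T,
                         frame_labels=df["label"].to_numpy(),
                         frame_times=df["time"].to_numpy(dtype=float),
                         meta=meta or {})


def write_design_csv(design: BlockDesign, path) -> None:
    df = design.to_frame()
    df.attrs = {}
    df.to_csv(path, index=False)


def read_design_csv(path, pair_tr: float = 5.02,
                    n_pairs: int | None = None) -> BlockDesign:
    df = pd.read_csv(path)
    runs = []
    for _, sub in df.groupby("run", sort=True):
        runs.append(RunDesign([Block(_maybe_int(c), float(o), float(d))
                               for c, o, d in zip(sub.condition, sub.onset,
                                                  sub.duration)]))
    kwargs = {} if n_pairs is None else {"n_pairs": n_pairs}
    return BlockDesign(runs, pair_tr=pair_tr, **kwargs)


def _maybe_int(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return c


def write_scenario_yaml(scenario: ScenarioSpec, path) -> None:
    payload = {"name": scenario.name, "noise_sd": scenario.noise_sd,
               "drift_amp": scenario.drift_amp, "bold_ratio": scenario.bold_ratio,
               "superficial_bias": scenario.superficial_bias,
               "gains": {r: {int(t): np.asarray(g).tolist()
                             for t, g in per.items()}
                         for r, per in scenario.gains.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_scenario_yaml(path) -> ScenarioSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    gains = {r: {int(t): np.asarray(g, dtype=float) for t, g in per.items()}
             for r, per in payload.pop("gains").items()}
    return ScenarioSpec(gains=gains, **payload)
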