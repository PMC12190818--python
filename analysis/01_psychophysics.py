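#!/usr/bin/env python
"""Behavioral sensitivity to a salient foreground.

Simulates 20 observers doing the 2AFC foreground-localization task (bars at
90 or 15 deg orientation contrast to the background texture), runs four
60-trial 3-down-1-up staircases per condition, fits Weibull psychometric
functions, and tests whether contrast sensitivity S = 1/C_threshold is
higher for the more salient (90 deg) foreground.

Writes results/psychophysics_fits.csv and results/psychophysics_summary.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lamsal import psychophys as pp
from lamsal.stats import paired_t

S90_TRUE, S15_TRUE = 18.719, 9.720   # group-mean generative sensitivities


def main(seed: int, out: Path) -> None:
    root = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(root.spawn(20)):
        rng = np.random.default_rng(child)
        subject_factor = np.exp(rng.normal(0.0, 0.15))
        for theta, s_base in ((90, S90_TRUE), (15, S15_TRUE)):
            s_true = s_base * subject_factor * np.exp(rng.normal(0.0, 0.08))
            obs = pp.make_weibull_observer(1.0 / s_true, slope=3.0)
            trials = pd.concat([pp.run_staircase(obs, theta=theta,
                                                 staircase_id=j, rng=rng)
                                for j in range(4)], ignore_index=True)
            fit = pp.fit_weibull(trials, theta=theta)
            rows.append({"subject": i, "theta": theta, "s_true": s_true,
                         "threshold": fit.threshold, "slope": fit.slope,
                         "sensitivity": fit.sensitivity})
    fits = pd.DataFrame(rows)
    wide = fits.pivot(index="subject", columns="theta", values="sensitivity")
    test = paired_t(wide[90], wide[15])
    ss = pp.behavioral_saliency_sensitivity(wide[90].mean(), wide[15].mean())

    out.mkdir(parents=True, exist_ok=True)
    fits.to_csv(out / "psychophysics_fits.csv", index=False)
    summary = {"mean_sensitivity_90": round(wide[90].mean(), 3),
               "mean_sensitivity_15": round(wide[15].mean(), 3),
               "mean_ss_behavior": round(ss, 3),
               "paired_t": {k: round(v, 4) for k, v in test.items()}}
    (out / "psychophysics_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"Sensitivity to the 90-deg foreground: {wide[90].mean():.2f}; "
          f"to the 15-deg foreground: {wide[15].mean():.2f}")
    print(f"Saliency advantage SS_behavior = {ss:.2f}; paired t({test['dof']}) = "
          f"{test['t']:.2f}, p = {test['p']:.2e}")
    print("Higher orientation contrast -> higher contrast sensitivity, "
          "as expected for a salient foreground.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.out)
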