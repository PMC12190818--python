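# lamsal — laminar VASO-fMRI analysis of visual saliency

A salient object — say, a patch of bars tilted 90° against a uniformly
oriented background — captures attention automatically, but *where* the brain
computes that saliency signal is contested: parietal cortex (feeding back to
V1), V1 itself (via horizontal connections in its superficial layers, feeding
forward to the middle layers of the intraparietal sulcus), or the superior
colliculus (via the tecto-thalamic route). Each account predicts a distinct
*laminar* profile of saliency-sensitive activity in V1 and IPS, which
cortical-depth-resolved CBV fMRI (VASO at 7 T) can in principle distinguish.

`lamsal` is a simulation-plus-analysis package for this experimental logic,
for researchers designing or interpreting laminar fMRI studies of bottom-up
attention. It provides:

* a **synthetic-data generator** producing interleaved blood-nulled /
  not-nulled laminar timeseries under the three origin scenarios, with known
  gains, BOLD (T2*) contamination, drift and noise, plus simulated Weibull
  observers, pRF tables and gaze traces;
* the **analysis chain**: BOLD correction (nulled / not-nulled division),
  percent-signal-change scaling, block GLM; equi-volume layer weights and
  spatial unmixing; the normalized response
  `S_fMRI(s,l,θ) = r(s,l,θ)/r_norm(s) · r̄` (with `r_norm(s)` the RMS over
  the layer×condition cells and `r̄` its group mean) and the
  saliency-sensitive response `SS_fMRI = S_fMRI(90°) − S_fMRI(15°)`;
* **statistics**: repeated-measures ANOVA with Greenhouse–Geisser correction,
  paired t with Holm correction, Pearson brain–behavior correlation with
  max-statistic permutation FWE across ROIs;
* **layer-specific gPPI** connectivity without deconvolution, the
  **pRF visual-field back-projection** of saliency maps per depth,
  **3-down-1-up staircase** psychophysics with Weibull fitting
  (`S = 1/C_threshold`, threshold at 80 % accuracy), and **95 % BCEA**
  fixation-stability metrics.

The modelling choices and their rationale are in `docs/methods.md`.

## Layout

```
src/lamsal/      library: design, synth, preproc, laminar, stats,
                 connectivity, fieldmap, eyetrack, psychophys, pipeline, io
analysis/        numbered study drivers (01_psychophysics ... 07_scenario_recovery)
tests/           unit, property and study-level tests
scripts/         acceptance.py (see "Reproducing the headline numbers")
```

## Worked example

Simulate and analyze a complete 20-subject study under the V1-origin
scenario, then correlate brain and behavior:

```bash
python analysis/02_laminar_profiles.py --seed 7
python analysis/03_brain_behavior.py  --seed 7
```

prints

```
Inferred generative scenario: v1sh
V1: strongest SS_fMRI layer = superficial (depth rmANOVA F(2,38) = 37.21, p = 0.0000)
V2: strongest SS_fMRI layer = superficial (depth rmANOVA F(2,38) = 11.91, p = 0.0001)
IPS: strongest SS_fMRI layer = middle (depth rmANOVA F(2,38) = 32.89, p = 0.0000)
V1 superficial vs deep: t = 7.60, p = 0.0000
...
Brain-behavior correlations (SS_fMRI at the strongest depth vs SS_behavior):
  V1 (superficial): r = +0.660, raw p = 0.0010, FWE p = 0.0018
  ...
FWE threshold (95th pct of max-r null): r = 0.465
```

Reading this: the depth-resolved chain recovered the generative scenario —
saliency-sensitive CBV responses peak in *superficial* V1 and *middle* IPS,
the feedforward signature — the depth differences are highly reliable across
the 20 simulated subjects, and subjects with stronger normalized saliency
responses also have higher behavioral sensitivity to saliency
(`SS_behavior = S(90°) − S(15°)`), surviving permutation FWE (observed r
above the 0.465 max-null threshold). The remaining drivers cover the
psychophysics (01), gPPI pathways (04), per-depth visual-field maps (05),
fixation stability (06) and the scenario-recovery confusion matrix (07); all
write their tables under `results/`.

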