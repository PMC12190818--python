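# Methods

`lamsal` simulates and analyzes cortical-depth-resolved VASO-CBV fMRI
experiments on visual saliency. This note documents the generative model, the
analysis chain, the defaults that matter, and what the simulations do and do
not establish.

## Scientific setting

A foreground patch of bars embedded in a uniformly oriented background texture
is salient in proportion to its orientation contrast θ (90°, 15°, 0°).
Competing accounts place the *origin* of the saliency signal in parietal
cortex (reaching V1 by feedback), in V1 itself (via horizontal connections in
the superficial layers, feeding forward to the middle layers of IPS), or in
the superior colliculus (reaching cortex through the tecto-thalamic route).
Each account predicts a different laminar profile of saliency-sensitive
activity in V1 and IPS, so depth-resolved fMRI can in principle distinguish
them. The package encodes the three accounts as generative scenarios and asks
whether the full analysis chain recovers them.

## Synthetic acquisition

* **Design.** Runs of 270 s: six 30-s stimulus blocks (two per θ), each
  preceded by 15 s fixation. Frames alternate blood-nulled / not-nulled every
  2.51 s (paired TR 5.02 s); onsets are snapped to the frame grid. Condition
  order is permuted per run; the canonical condition order (90, 15, 0) is
  carried on the design object so tables are comparable across subjects.
* **Cortical geometry.** A cortical patch is an annular wedge between a WM
  radius and a pial radius (default 10.0 and 12.5 arbitrary units; the
  thickness/radius ratio sets the curvature). Equi-volume laminar boundaries
  for cumulative volume fraction α are `r(α) = sqrt(α·pial² + (1−α)·wm²)` for
  the 2D wedge, with a 3D spherical-shell variant
  `r(α) = (α·pial³ + (1−α)·wm³)^{1/3}` behind the `geometry` flag. A square
  voxel grid (voxel edge = thickness/6 by default) is intersected with the
  wedge; each voxel's weights over {WM, CSF, deep, middle, superficial} are
  volume fractions obtained by 16×16 sub-voxel sampling.
* **Scenario gains** (% signal change, CBV channel, θ = 90°):

  | scenario           | V1 (D,M,S)      | V2 (D,M,S)      | IPS (D,M,S)     |
  |--------------------|-----------------|-----------------|-----------------|
  | v1sh               | 0.3, 0.4, 1.0   | 0.3, 0.7, 0.9   | 0.3, 1.0, 0.4   |
  | feedback_parietal  | 1.0, 0.3, 0.8   | 1.0, 0.3, 0.8   | 1.0, 0.3, 0.3   |
  | sc_tectothalamic   | 0.3, 1.0, 0.8   | 0.3, 1.0, 0.8   | 0.3, 1.0, 0.8   |

  The 15° condition scales the 90° gains by 0.4; the 0° condition is a flat
  0.25 % (texture onset without a salient foreground). Only the orderings are
  constrained by theory; the magnitudes are package defaults exposed in the
  scenario configuration. V2 follows the qualitative expectation for each
  account (for the V1-origin case, middle+superficial).
* **Signal model.** Per voxel, with layer-weight vector w and gain g(θ)
  mixed as a = w·g, the condition responses are x_θ(t): 30-s boxcars
  convolved with a double-gamma HRF (peak 5 s, undershoot 15 s, ratio 6),
  normalized to unit plateau. Then

      notnulled(t) = V0 · B(t),          B(t) = 1 + Σ_θ b_θ x_θ(t)/100
      nulled(t)    = V0 · (1 − Σ_θ a_θ x_θ(t)/100) · B̃(t)

  where b = `bold_ratio`·a is the BOLD gain and B̃ is the not-nulled BOLD
  factor resampled to the nulled frame times *with the same stencil the
  analysis uses*. Modelling the T2* contamination of the nulled frames this
  way makes the BOLD-correction division cancel it exactly at the acquired
  timepoints; contamination defined in continuous time is cancelled only
  approximately after discrete resampling, and that looser case is tested
  separately. `bold_ratio` defaults to 0.7: with full multiplicative
  contamination, a ratio ≥ 1 would make the raw nulled signal *rise* during
  activation, contradicting the VASO convention that activation lowers the
  nulled signal.
* **Noise.** Additive white Gaussian noise per frame (`noise_sd`, default
  0.5 % of baseline — a depth-resolved-fMRI-like voxel SNR) and per-run
  random Legendre drifts of orders 1–3 (`drift_amp`, default 0.5 %),
  independent per stream. An optional `superficial_bias` slope emulates
  draining-vein amplification of the BOLD channel (default off).
* **Subjects.** Each subject gets a lognormal overall amplitude factor
  (σ = 0.3; removed again by the normalization) and a lognormal *saliency*
  factor (σ = 0.3) scaling the 90° gains in all regions; the same factor
  scales the subject's true behavioral sensitivity at 90°, so a real
  brain–behavior correlation exists for the analysis to find.

## Analysis chain

1. **Split & align.** The interleaved series is separated into nulled and
   not-nulled streams and up-sampled ×2 onto the common frame grid; because
   missing points are exact midpoints, resampling uses a 4-point
   cubic-Lagrange midpoint stencil (−1/16, 9/16, 9/16, −1/16), exact for
   cubic polynomials (≈0.6 % RMS error on a sinusoid of period 8 paired-TRs),
   with linear/edge-hold fallbacks near run boundaries. Runs are never
   interpolated across.
2. **BOLD correction.** VASO = nulled / not-nulled, elementwise on the common
   grid; voxels with a non-positive denominator are masked with a warning.
3. **Percent signal change** per run around the run-mean baseline.
4. **GLM.** Ordinary least squares per run with HRF-convolved condition
   regressors (the same forward model as the simulator) and per-run Legendre
   drifts (order ≤ 3); optional motion columns. Condition betas are estimated
   at each stream's *native* timepoints (VASO on the nulled grid, BOLD on the
   not-nulled grid): the interpolated half-grid points are linear
   combinations of the native ones and would re-introduce interpolation bias.
   The CBV response is the negated VASO beta (positive during activation).
5. **Mean-scale correction.** Scaling by the run mean divides all effects by
   the mean of the ratio, which itself contains the condition responses;
   solving the fixed point gives the closed-form correction
   `g = β / (1 + Σ_θ β_θ x̄_θ / 100)` (sign flipped for the BOLD stream).
   Betas are corrected per run, then averaged across runs. With noise and
   drift at zero the whole chain then returns the generative gains to
   machine precision, which is how amplitude fidelity is tested.
6. **Layer unmixing.** Voxel betas are regressed on the voxel×compartment
   weight matrix (OLS, no non-negativity constraint); WM and CSF act as
   nuisance compartments; rank deficiencies raise with the unidentifiable
   compartments named. ROI selection takes voxels with positive localizer
   activation at one-sided p < .05 (uncorrected) within the anatomical label.
7. **Normalization.** r_norm(s) is the RMS of r(s, l, θ) over the nine
   layer×condition cells, r̄ its group mean, and
   S(s,l,θ) = r(s,l,θ)/r_norm(s)·r̄; the saliency-sensitive response is
   SS(s,l) = S(s,l,90°) − S(s,l,15°), which cancels background-suppression
   partial-volume effects shared by the two foreground conditions.
8. **Inference.** Two-way within-subject ANOVA (depth × θ, via pingouin) and
   a closed-form one-way rmANOVA, both with Greenhouse–Geisser correction
   applied when Mauchly's test rejects sphericity (p < .05); paired t-tests
   with Holm correction. Brain–behavior: Pearson r between SS_behavior and
   SS_fMRI at each ROI's strongest depth (chosen on the group mean), with
   family-wise error over ROIs controlled by the permutation distribution of
   the maximum r (10,000 permutations by default; signed max by default, |r|
   behind a flag; p-values use the +1 permutation convention).
9. **gPPI.** No deconvolution: the PPI term is the seed timecourse times the
   condition boxcar shifted by one paired TR (5.02 s; configurable). The
   target GLM has the seed, shifted boxcars, three PPI terms, and drifts;
   saliency-dependent connectivity is Δ = β_PPI(90°) − β_PPI(15°), tested
   across subjects with paired t and Holm over the two default pathways
   (V1 superficial → IPS middle; IPS deep → V1 deep). Connectivity runs on
   the not-nulled (BOLD) stream by default. In the orchestrated study the
   seed/target series are simulated at ROI level with coupling contrasts of
   0.3 (coupled pathway) vs 0 and ROI-mean noise `noise_sd/√n_voxels`.
10. **Field maps.** Each surface node's SS response is multiplied into its
    isotropic Gaussian pRF and summed over nodes on a 0.1° lattice of the
    lower visual field; pRF centers are translated so the localizer peak
    lands on the true foreground location; depth maps are divided by the
    single maximum across depths, then averaged over subjects. pRFs are
    unnormalized (peak 1) by default, with a normalized-integral flag.
11. **Eye tracking.** Blink samples ±200 ms are removed and linearly
    interpolated, traces are linearly detrended and baseline-corrected per
    block; fixation stability is the 95 % bivariate contour ellipse area
    BCEA = 2πk σ_x σ_y √(1−ρ²) with k = −ln(1−0.95) ≈ 2.9957 (the
    P = 1 − e^{−k} convention).

## Psychophysics

The 2AFC observer follows a Weibull psychometric function
P(c) = 0.5 + (0.5 − lapse/2)(1 − e^{−(c/α)^β}); the threshold is the contrast
at 80 % accuracy and sensitivity is S = 1/C_threshold. Staircases are
3-down-1-up (converging at 0.5^{1/3} ≈ 79.4 % correct) with multiplicative
steps of 0.1 log₁₀ units before the second reversal and 0.05 after, bounded
by the luminance-feasible contrast range of the reference display (Michelson
contrast ≤ 0.28606, from bar luminances 43.8–78.9 cd/m²). Fitting is maximum
likelihood over (α, β) with guess fixed at 0.5 and lapse fixed at 0.01
(bounded L-BFGS from a small start grid; ties broken toward the shallower
slope). Four 60-trial staircases per condition match the reference protocol;
threshold readout at the 80 % point of the fitted curve lands on the
simulated observer's true 80 %-correct contrast to within 2 percentage points
on average.

## Scenario classification

A study's laminar signature is the group-mean SS profile in V1 and IPS. The
classifier normalizes each region's 3-vector to unit length and picks the
scenario whose template (gain(90°) − gain(15°) per region, similarly
normalized) has the largest summed cosine similarity. With 20 subjects at the
default noise this recovers the generative scenario in ≥ 95 % of replicates;
accuracy is 1.0 without noise and collapses toward chance (1/3) when the
noise SD is an order of magnitude above the gains.

## Simulation sizes

Scenario-recovery and group experiments use 2 runs per subject and 18–24
voxels per region (the reference acquisition had 9 runs and a full imaging
slab); the Monte-Carlo power target uses 5,000 replicates, the FWE check
1,000 experiments × 5,000 permutations, and the threshold-criterion check 200
simulated participants. These are the package's chosen problem sizes and are
stated here so results are interpreted at that scale.

## Limitations

* The generator has no EPI distortion, motion, slice-timing structure beyond
  the TR/2 interleave, physiological noise spectra, or vascular biophysics
  beyond the sign convention and the optional superficial bias; passing tests
  show the *chain* is correct and the *design* is decodable under this model,
  not that real data meet its assumptions.
* The subject saliency factor scales all regions together, so simulated
  brain–behavior correlations appear in V1, V2 and IPS alike; region-specific
  correlation (as opposed to correlation per se) is not a property the
  generator encodes.
* The spatial-unmixing reading (OLS over volume-fraction weights) is one
  interpretation of layer-weight regression; it is configurable and tested
  for identifiability, not asserted as the only choice.
* Staircase step sizes, start values, and the fixed lapse are defaults where
  the reference protocol is silent; they are exposed as parameters.
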