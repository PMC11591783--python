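# Methods

This note documents the models and procedures implemented in `satrain`,
the assumptions behind the synthetic cohort generator, and the numerical
choices made where the underlying study protocol leaves the design open.

## 1. SA labeling model

### RT standardization

Response times of the *pooled* cohort (not per subject or condition) are
standardized before mixture fitting; a single global threshold is the
target of the analysis. The default is z-scoring with the sample SD
(ddof = 1); min-max scaling to [0, 1] is available via
`standardize_rt(..., mode="minmax")`. The transform is affine and
invertible, so thresholds round-trip exactly between standardized units
and seconds (asserted to 1e-9 in tests).

### Two-component Gaussian mixture

`fit_gmm_1d` implements EM for a univariate k = 2 mixture:

* initialisation by median split (component statistics of the lower and
  upper halves), plus 4 seeded restarts that jitter the initial means by
  0.25 SD; best final log-likelihood wins;
* responsibilities computed from weighted normal densities with the total
  floored at 1e-300 to avoid log(0);
* variances floored at 1e-6 (degenerate clusters collapse to the floor
  rather than diverging);
* convergence when the relative log-likelihood change is below 1e-6
  (max 500 iterations; non-convergence returns `converged=False` rather
  than raising);
* components returned sorted by mean.

EM's monotone log-likelihood and recovery of generating parameters
(|Δμ| < 0.1, |Δw| < 0.05 at n = 2000) are tested, and the fit is
cross-checked against an independent library implementation.

### Density-intersection threshold

The RT cutoff solves `w1 φ(x; μ1, σ1²) = w2 φ(x; μ2, σ2²)` via the
quadratic in `x` obtained from the log densities, keeping the root
strictly between the component means. The *weighted* intersection is the
default — it is the Bayes decision boundary of the fitted mixture — with
the unweighted variant available by flag. If no root lies between the
means (possible under extreme weight imbalance), the argmin of the
absolute density difference on a 10,001-point grid over [μ1, μ2] is used
and flagged as a fallback. Equal component means raise a degenerate-model
error.

### Fusion rule and dichotomizations

"Exceeds" is read as strict `>` for both the RT threshold and the score
median; boundary values (RT exactly at the cutoff, score exactly at the
median) therefore label **high** SA. The block-level subjective score
applies to all eight trials of its block. A missing score is an error
unless the RT alone already decides (RT above cutoff). Fatigue is KSS ≥ 6,
stress is SATI-6 ≥ 15; both are carried alongside the SA label.

Note a structural property of the median fusion rule: roughly half of all
blocks exceed the cohort median score by construction, so the labeled
low-SA share always exceeds the latent low-SA rate. On the default
synthetic cohort about 36% of trials are latently low-SA while ~55–58%
are labeled low; the condition gradient (LL < LH ≈ HL < HH) is preserved,
which is what the chi-square validation tests.

## 2. Synthetic cohort generator

The generator emulates the study design the analysis assumes: 19
subjects × 4 conditions × 3 blocks × 8 events = 1824 trial segments,
gaze at 15 Hz, ECG at 512 Hz, 32-channel EEG at 256 Hz, segment
durations uniform on [30, 60] s. Per-condition low-SA probabilities
default to the reference distribution (LL 102/412, LH 151/422,
HL 153/430, HH 207/441). Event order within a block cycles a Latin-square
row by default (a seeded random permutation is the alternative); block
and condition order are counterbalanced across subjects by rotation.

### Response times

RTs are positive and right-skewed, so each SA state draws from a
lognormal truncated below 0.5 s: high SA median 3.0 s (σ_log 0.32), low
SA median 10.0 s (σ_log 0.10). These values were calibrated once so that
the *fitted* weighted-density intersection on a pooled cohort lands in
the mid-6-second range (the design window is 5.5–7.5 s); with equal log
spreads on both components the raw-scale SD of the slow component is
several times that of the fast one and the fitted intersection falls
near 4.6 s instead, outside the window. The calibration is a property of
the generator's design, fixed before use, and configurable.

### Subjective scores

KSS is drawn ≥ 6 iff the condition induces fatigue (HL, HH) and ≤ 5
otherwise; SATI-6 ≥ 15 iff the condition induces stress (LH, HH). Each
block's fatigue/stress state flips with probability 5% (crossover
noise), mirroring the observation that low SA occurs even under LL. The
adapted-MARS SA score uses an 8–32 range (8 items × 4 points) and rises
with the block's realised low-SA fraction: `round(N(12 + 8·frac, 2))`
clipped to range. The +8 slope makes block scores informative but noisy,
as subjective ratings are.

### Gaze

Streams alternate fixations (0.25–0.9 s, within-fixation jitter
N(0, 0.08°) clipped at ±0.4°) and saccades (≥ 3° steps between
consecutive samples, intermediate points inserted for long jumps).
Fixation targets fall inside three axis-aligned AOI rectangles defined
in degrees of visual angle — View Scene spanning the upper field, DMI
lower-left, MMI lower-right — drawn with state-dependent probabilities:
high SA {View Scene 0.6, MMI 0.2, DMI 0.2}, low SA {0.3, 0.35, 0.35}.
Consecutive fixation centres are kept ≥ 4° apart so every saccade
crosses the 30°/s velocity threshold. 2% of samples are invalidated by
default to exercise gap interpolation.

### ECG

RR intervals follow `base + A_lf sin(2π·0.1t) + A_hf sin(2π·0.25t) +
N(0, σ_j)`, clipped to [300, 2000] ms. High SA: 72 bpm, A_lf = A_hf =
45 ms, σ_j = 15 ms (SDNN ≈ 48 ms); low SA: 84 bpm, A = 20 ms, σ_j =
10 ms (SDNN ≈ 22 ms) — lower heart rate and larger variability under
high SA. The waveform places a stereotyped P-QRS-T template (five
Gaussians, R amplitude 1 mV) at each R time over 0.02 mV white noise,
and ground-truth R times are returned for detector validation. The
morphology is deliberately minimal: realistic enough for peak detection,
not for beat classification.

### EEG

Per channel: pink (1/f-amplitude) background noise at 4 µV RMS with a
uniform ×[0.7, 1.4] per-channel gain (cross-channel variance would
otherwise be unrealistically homogeneous and break robust bad-channel
statistics), plus band oscillations with random phase: theta 6 Hz on
frontal channels (6 µV high SA / 3 µV low), alpha 10 Hz on
frontal+parietal (3 / 6 µV — larger under *low* SA), beta 20 Hz on
frontal+parietal (4 / 2 µV). Channel names follow a standard
32-electrode 10-20 montage. No ocular or muscle artifacts are generated
(artifact removal by component inspection is a manual step outside this
package's scope), so passing tests demonstrate correctness of the
spectral pipeline, not robustness to artifacted field data.

### What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — bimodal RTs, condition-dependent label rates, SA-dependent
physiological shifts in the reported directions. It does not reproduce
real-data nuisances: non-stationarity, artifacts, missing blocks,
individual-difference distributions. Tests passing on synthetic cohorts
validate the implementation, not the field applicability of the method.

## 3. Signal-processing choices

* **Gaze.** Gaps ≤ 75 ms (measured as run length / rate) are linearly
  interpolated when bounded by valid samples; leading/trailing gaps are
  never filled. The median filter (window 3) runs per maximal valid run
  with shrunken windows at run edges. Velocity is a two-point backward
  difference (15 Hz is too sparse for higher-order estimators); the
  sample after a gap has undefined velocity. I-VT uses strict `v > 30°/s`
  for saccades. Fixation events require ≥ 60 ms span; AOI membership is
  half-open `[min, max)`; heatmap kernels are truncated-renormalised so
  the grid mass equals total fixation duration.
* **ECG.** The 0.05–100 Hz zero-phase band-pass is applied as a squared
  order-4 Butterworth magnitude in the frequency domain: a time-domain
  IIR realisation of a 0.05 Hz corner at 512 Hz places poles within 1e-5
  of the unit circle and is numerically fragile, while the spectral form
  has the identical magnitude response of forward-backward filtering.
  Wavelet denoising: Daubechies-4, 6 levels, soft universal threshold
  σ√(2 ln N) with σ = MAD(finest details)/0.6745. R peaks: Pan-Tompkins
  style (5–25 Hz detection band, derivative, squaring, 150 ms moving
  integration, adaptive signal/noise thresholds, 250 ms refractory,
  refinement to the filtered-ECG maximum within ±50 ms). RR artifacts
  (outside [300, 2000] ms or > 25% off the 11-beat running median) are
  interpolated before feature extraction.
* **HRV.** SDs use ddof = 1; pNN50 counts strictly |Δ| > 50 ms. The
  tachogram is cubic-interpolated to 4 Hz; Welch uses 30-s Hann windows,
  50% overlap, linear detrend. Band edges follow the short-term HRV
  convention (LF 0.04–0.15, HF 0.15–0.40 Hz); total power is 0.04–0.40 Hz
  because VLF is unresolvable in 30-s windows. The window-length check
  uses the recorded segment duration (the R-peak span is necessarily
  slightly shorter; Welch clamps its segment length to the data).
* **EEG.** Fixed order: bad-channel detection (robust log-variance
  z > 4 or peak-to-peak < 0.1 µV; > 25% bad rejects the segment) →
  spherical-spline interpolation (standard montage positions) → common
  average reference → zero-phase 1–30 Hz Butterworth → non-overlapping
  1-s epochs (remainder dropped) → Hann periodogram per epoch at 1 Hz
  resolution → band integration → epoch average. Band-edge ownership is
  lower-inclusive/upper-exclusive (beta's 30 Hz upper edge inclusive).
  Band powers are integrated (µV²), not densities. Regional summaries
  use standard montage groupings: frontal {Fp1, Fp2, F3, F4, F7, F8,
  Fz}, parietal {P3, P4, P7, P8, Pz}, occipital {O1, O2}, remainder
  central/temporal.

## 4. Validation statistics

The omnibus test is the uncorrected Pearson chi-square on the k × 2
table (df = k−1); pairwise 2×2 comparisons apply the Yates continuity
correction with the clamp at zero — this pairing exactly reproduces the
reference statistics (the uncorrected 2×2 form does not, e.g. LL vs HH
would give 45.36 instead of 44.41). Raw pairwise p-values are reported
with Bonferroni-adjusted values alongside. Mann-Whitney U uses midranks
with the exact null for tie-free samples of ≤ 20, otherwise the normal
approximation with continuity and tie correction; Wilcoxon signed-rank
drops zeros, midranks |d|, reports min(W+, W−), exact for n ≤ 25
tie-free, normal approximation otherwise. Both are calibrated under the
null (type-I error within [0.03, 0.07] at nominal 0.05, 10,000 reps).

## 5. Problem sizes in bundled checks

The acceptance-style tests use 2,000 draws for mixture recovery, 50
trials per SA state for HRV comparisons, 19 simulated subjects × 2
trials per state for the paired EEG comparisons (20-s segments), 10,000
null replicates at n = 30 for rank-test calibration, and 20 cohort seeds
for omnibus power; these sizes give stable verdicts for the effect sizes
the generator produces. The end-to-end pipeline caps raw-signal
synthesis at `max_signal_trials` (default 24) while the tabular design
stays full-size.

## 6. Known limitations

* The mixture model is fit on standardized raw RTs; a log-RT fit would
  be more natural for lognormal components but the analysis being
  reproduced standardizes RTs directly.
* Per-subject thresholds, >2 mixture components, and SAGAT/SART-style
  direct SA measures are out of scope.
* Linear mixed models for fatigue/stress time courses are not
  implemented (standard off-the-shelf fits); the generator still emits
  score trajectories.
* ECG morphology and EEG artifact content are intentionally simplified;
  see §2.
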