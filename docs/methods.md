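# Methods

This note documents the models and procedures implemented in `fatiguekit`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Signal model and feature chain

**Recording layout.** The default acquisition layout has 21 channels: 11
posterior (`EEG-P`) and 6 temporal (`EEG-T`) scalp leads plus 4 forehead
electrodes (`EOG`, positions left/right/upper/lower).  The frontal EEG area
(`F`, 4 leads) is read from the forehead electrodes through the montage
mapping, so the same electrodes serve EOG extraction and frontal EEG
features.  Electrode positions are a required declaration for EOG work
because the separation rules are position-specific.

**Rhythm bands.** δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz — the
conventional clinical definitions.  Band-pass filtering is a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero-phase with
an effectively squared magnitude response.  Adjacent bands cross at their
shared edge where each contributes half power, so summing the five band
outputs reconstructs 1–50 Hz broadband content with ≈ 12% relative L2 error
(crossover droop); a higher filter order would reduce the droop at the cost
of longer edge transients on 8 s epochs.

**Epoching.** Default epoch length 8 s, non-overlapping (stride
configurable).  A trailing partial window is dropped rather than padded,
keeping per-epoch variance estimates unbiased.  When a ground-truth state
track is present an epoch takes the majority state; an exact tie is assigned
to fatigue — the safety-conservative call for a warning system.

**Differential entropy (DE).** A band-limited EEG segment is modeled as
Gaussian, for which the entropy integral −∫ f ln f has the closed form
½ ln(2πe σ²).  Natural logarithm throughout (nats); σ² is the unbiased
(n−1) sample variance — immaterial at 8 s × 200 Hz but fixed for
reproducibility.  A constant segment returns −∞ with a warning.  DE is a
strictly increasing function of band power, which is why it carries the same
fatigue signature as PSD with better numerical conditioning at low power.

**Band PSD.** The mean periodogram density (µV²/Hz) within the band, from a
single Hann-windowed transform of the epoch by default; Welch-style
sub-window averaging is available via `nperseg`.  The per-band *mean* (not
sum) makes features comparable across bands of different widths.

**LDS smoothing.** Feature trajectories across epochs are smoothed under a
local-level state-space model (random-walk state plus observation noise) by
a Kalman forward pass and Rauch–Tung–Striebel backward pass, initialized at
the first observation with variance equal to the observation variance.
Defaults `process_var = 0.1`, `obs_var = 1.0` (a 10:1 smoothing ratio);
`obs_var → 0` reproduces the input, a constant series is a fixed point.
The implementation is verified against statsmodels' `UnobservedComponents`
local-level smoother in the test suite.

## EOG processing

**Separation.** Subtraction rule: `V = upper − lower`, `H = left − right`,
which cancels common-mode frontal EEG and drift exactly.  The BSS variant
runs FastICA on the four channels, keeps the two components best correlated
in absolute value with the subtraction traces, and sign/scale-aligns them to
those traces by least squares; rank-deficient or non-convergent inputs fall
back to the subtraction rule with a warning.  The mixed variant
(`icav_minh`) pairs the BSS vertical with the subtraction horizontal.

**Blink detection.** Continuous wavelet transform with the Mexican-hat
wavelet at 8 scales spanning blink half-durations of 0.1–0.5 s; the maximal
absolute coefficient across scales is thresholded at 3× its median absolute
deviation and peaks at least 0.2 s apart become events.  Around each apex the
event extends while the deflection exceeds 10% of its peak; the **closure
interval** is the span above half-peak.  Overlapping events merge.  Blinks
are assumed to be positive deflections on V (upper-minus-lower polarity).

**PERCLOS and labels.** P = closed time / window length, closures clipped to
the window; PERCLOS is exactly time-additive across window splits.  Label
rule: P < 0.35 → awake (0), P ≥ 0.35 → fatigue (1).  The threshold value
itself is assigned to fatigue: the published rule covers only the strict
inequalities, and for a warning system the conservative direction is to warn.

**Per-window EOG features.** blink rate (/min), mean/max blink duration (s),
mean peak amplitude (µV), PERCLOS, and the slow-eye-movement proportion —
the fraction of horizontal-trace spectral power below 0.5 Hz.  Windows with
no events report zero rates and durations, with PERCLOS still computed from
whatever closures intersect the window.

## The fast SVM

In the kernel feature space, `d(x_i, x_j) = √(K_ii − 2K_ij + K_jj)`, which
for unit-diagonal kernels is `√(2 − 2K_ij)` — bounded by √2, attained as the
kernel vanishes.  Negative radicands from floating-point noise are clamped
to zero.

With positives-first ordering, the distance matrix splits into blocks
D11/D12/D21/D22 and the per-point class means follow by multiplying each
block by the uniform weight vector of its class (V11 = D11·I_{l+} etc.).
The self-distance (zero) is *included* in the same-class mean — the mean
runs over all class members — with an exclude-self toggle deliberately
omitted because the shift is a constant per class and cannot change the
ranking order.

Selection per class at ratio r: intersect the top ⌈l_c·r⌉ points ranked by
same-class mean (descending) with the top ⌈l_c·r⌉ ranked by opposite-class
mean (ascending); ties break by ascending original index, so selection is
deterministic.  The ceiling guarantees each ranking nominates at least one
point for every r > 0.  If the intersection is empty (common at small r on
overlapping classes, where the same-class ranking favours far-side outliers)
the class falls back to its top ⌈l_c·r⌉ by ascending opposite-class mean —
proximity to the other class is the stronger boundary signal — so the
reduced set is never empty.  One consequence: the selected count is monotone
in r while the intersection rule operates (top-m sets are nested in m), but
a fallback at small r can exceed the intersection at a slightly larger r.

The union T_BD = T⁺ ∪ T⁻ is handed to a standard soft-margin SVM
(scikit-learn's SVC; re-deriving a QP solver would add nothing).  The
trained model stores the support vectors, dual coefficients and bias, and
evaluates its decision function from that kernel expansion directly, so a
JSON-serialized model reproduces predictions without the solver object.
At r = 1 every point is selected in original order and the model coincides
with the plain SVM to solver precision.

**Kernel and defaults.** RBF `K = exp(−γ‖·‖²)` with γ = 0.001 — the
published operating point for band-power/entropy feature tables, whose
squared pairwise distances are on the order of 10²–10³.  γ is a *length
scale* choice: on features living at a different scale it must be re-matched
(the end-to-end example uses the median heuristic
γ = 1/median ‖x_i − x_j‖²).  Soft-margin C defaults to 1.0 (unspecified in
the source method; exposed everywhere).  Class mapping: fatigue (1) is the
positive class.

## Evaluation protocol

Stratified random 7:3 train/test splits (stratification prevents
single-class test sets on small epoch counts), recognition accuracy
Acc = (TP+TN)/total with fatigue as positive, and 10 repetitions with
derived seeds `base_seed + run` whose per-run values, means, and
solver-input sizes all land in the report.  `compare_models` runs the fast
SVM over a ratio grid against the plain-SVM baseline on *identical* splits,
so differences are paired.  Training time is a hardware property and is
never asserted; the solver-input size is the portable proxy for it.

## Synthetic data: what it does and does not emulate

`simulate_recording` produces, from one splittable seed:

* EEG channels as sums of band-limited Gaussian noise whose per-band power
  switches with the programmed state: awake (δ,θ,α,β,γ) =
  (10,4,5,8,2) µV², fatigue (10,9,11,3,2) µV² — θ/α up, β down, the classic
  drowsiness signature — plus white sensor noise (default 1 µV).
* Forehead channels sharing an attenuated frontal EEG and a slow drift;
  raised-cosine blink deflections (default 300 µV) on the upper electrode
  and an antisymmetric slow-eye-movement dipole on the left/right pair.
  A raised cosine exceeds half-peak for exactly half its support, so a blink
  of total width 2τ contributes exactly τ of eye closure; blinks are placed
  quasi-periodically (±5% jitter, clamped inside state segments) so every
  epoch's closure fraction tracks the programmed rate·duration/60: awake
  10/min × 0.2 s → 0.033, fatigue 30/min × 1.0 s → 0.5.
* A per-sample ground-truth state track and the exact closure intervals.

Defaults: fs = 1000 Hz (the standard acquisition rate for this setup);
tests and the acceptance script simulate at 200 Hz and tens of seconds —
the statistical structure, not the scale, is what the checks exercise.
Bands above the simulation Nyquist are silently dropped (γ at fs < 111 Hz).

The two-Gaussian feature testbed (`simulate_feature_dataset`) places
isotropic clouds (default sd 10) at class-mean distance `separation`
(default 30 = 3 sd) along the first axis.  The sd-10 default puts squared
distances on the order of 1/γ for the default kernel — the regime the
selection statistics are meant for; at unit scale the γ = 0.001 kernel is
numerically flat and any kernel method degrades.

**Not emulated:** real EEG artifacts (EMG, line noise, electrode pops),
1/f background spectra, saccades and eyelid-tracking detail, inter-subject
variability, and any hardware/transport layer.  Passing tests therefore
demonstrate the correctness of the *algorithms* — feature algebra,
selection, training, labeling — under the assumed signal structure, not
field performance on real drivers.

## Known limitations

* The selection ranks once on the full distance matrix (O(l²) memory);
  for very large l a blocked or approximate-neighbor variant would be
  needed — out of scope here.
* EDF support is a minimal 16-bit codec (written files are read back by
  mne, which the tests verify); annotations beyond the state-track channel
  and non-integer record geometries are not supported — use the CSV dialect
  for exotic cases.
* Blink detection assumes positive vertical deflections and one dominant
  blink morphology; heavily asymmetric or saturated blinks would need a
  recalibrated threshold.
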