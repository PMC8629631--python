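# fatiguekit

Driver-fatigue recognition from EEG and EOG signals, built around a **fast
support vector machine** that prunes the training set before the solver ever
sees it.

Long monotonous driving shifts the EEG toward slow rhythms — θ (4–8 Hz) and
α (8–13 Hz) power rise while β (13–30 Hz) falls — and the eyes stay closed a
growing fraction of the time. `fatiguekit` implements the full recognition
chain that exploits this:

* **EEG band features** — each 8 s epoch is decomposed into the five rhythm
  bands δ, θ, α, β, γ (zero-phase Butterworth filters) and summarized per
  (channel, band) by either the mean band power spectral density (PSD,
  µV²/Hz) or the **differential entropy** of the band-limited signal under a
  Gaussian model,

  ```
  h = ½ ln(2πe σ²)     [nats]
  ```

  optionally smoothed across epochs by a linear-dynamic-system (local-level
  Kalman/RTS) smoother.
* **EOG features and labels** — horizontal/vertical traces from the four
  forehead electrodes (subtraction rule `V = upper − lower, H = left − right`
  or FastICA blind source separation), Mexican-hat wavelet blink detection,
  and **PERCLOS**

  ```
  P = eye_closing_time / total_time
  ```

  with the binary vigilance label `P < 0.35 → awake (0)`, otherwise
  `fatigue (1)`.
* **Fast SVM (FSVM)** — support vectors live on the class boundary, so in
  kernel feature space they have a *large* mean distance to their own class
  and a *small* mean distance to the other class.  With the unit-diagonal
  RBF kernel the pairwise distance is `d(xᵢ,xⱼ) = √(2 − 2K(xᵢ,xⱼ))`.  Per
  class, the top `⌈l·r⌉` points of the same-class ranking (descending) are
  intersected with the top `⌈l·r⌉` of the opposite-class ranking
  (ascending); the union over classes, `T_BD`, is handed to a standard
  soft-margin SVM.  The solver trains on at most `⌈l⁺r⌉ + ⌈l⁻r⌉` points —
  at `r = 1` the method is exactly the plain SVM.
* **Synthetic data** — a seeded simulator generates 21-channel recordings
  (11 posterior + 6 temporal EEG leads and 4 forehead electrodes) with the
  programmed band-power shifts, blink trains and ground-truth state track,
  so the whole chain is testable without any recording hardware or dataset
  download.  Recordings round-trip through EDF and a CSV dialect.

## Worked example

`examples/end_to_end_pipeline.py` runs the whole chain on a simulated ~13 min
drive — EEG differential-entropy features per 8 s epoch, PERCLOS labels from
the EOG, then fast-SVM vs plain-SVM evaluation on stratified 7:3 splits:

```
96 epochs, 48 fatigue / 48 awake (labels from PERCLOS >= 0.35)
median-heuristic RBF gamma = 10.5
fast SVM (r=0.5): mean accuracy 0.9724, solver size 16
plain SVM       : mean accuracy 0.9621, solver size 67
```

The fast SVM matches the plain SVM's recognition accuracy while the solver
trains on 16 points instead of 67 — the training-time saving is the point of
the pre-selection.  The other examples isolate single capabilities:
`simulate_and_label.py` (PERCLOS labeling; the fatigue half of the recording
shows P ≈ 0.5, the awake half P ≈ 0.03), `eeg_band_features.py` (the θ/α-up,
β-down fatigue signature in DE features), and `fast_svm_comparison.py`
(accuracy vs solver size across the ratio grid, where `r = 1` reproduces the
plain SVM exactly).

A thin CLI covers the same chain from the shell:

```sh
fatiguekit --seed 1 simulate rec.csv --duration 64 --fs 200
fatiguekit extract-eeg rec.csv eeg.csv --kind DE
fatiguekit extract-eog rec.csv eog.csv --variant minus
fatiguekit train features.csv model.json --ratio 0.5 --gamma 0.001
fatiguekit compare features.csv --r-grid 0.3,0.5,1.0
```

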