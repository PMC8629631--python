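"""Full recognition chain: simulate -> features -> PERCLOS labels -> fast SVM.

Simulates a long recording, extracts posterior-area differential-entropy
features per 8 s epoch, labels each epoch from the EOG via PERCLOS, then
trains the fast SVM on a 7:3 split and reports recognition accuracy
Acc = (TP+TN)/(TP+TN+FP+FN).
"""

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from fatiguekit import (
    KernelSpec,
    LabeledDataset,
    ModelSpec,
    SimulationConfig,
    default_eog_positions,
    detect_blinks,
    extract_eeg_features,
    extract_eog_features,
    repeated_eval,
    separate_hv,
    simulate_recording,
)

# 24 alternating awake/fatigue segments of 32 s each (~13 min of driving)
schedule = [(s % 2, 32.0) for s in range(24)]
cfg = SimulationConfig(duration_s=768.0, fs=200.0, state_schedule=schedule, seed=3)
rec = simulate_recording(cfg)

# EEG features per epoch (posterior area, DE with LDS smoothing)
eeg = extract_eeg_features(rec, montage={"P": rec.by_role("EEG-P")},
                           kind="DE", smooth=True)

# EOG-derived PERCLOS labels per epoch
eog = {pos: rec.get(name) for pos, name in default_eog_positions(rec).items()}
h, v = separate_hv(eog)
events = detect_blinks(v, rec.fs)
eogf = extract_eog_features(h, v, rec.fs, events=events, window_len_s=8.0)

X = eeg.drop(columns=["epoch_start_s", "label"]).to_numpy()
y = eogf["label"].to_numpy()[: len(X)]
ds = LabeledDataset(X=X, y=y)
print(f"{len(ds)} epochs, {ds.l_pos} fatigue / {ds.l_neg} awake "
      f"(labels from PERCLOS >= 0.35)")

# the RBF width must match the feature scale: the median heuristic sets
# gamma = 1 / median(squared pairwise distance) of the feature vectors
gamma = float(1.0 / np.median(euclidean_distances(X) ** 2))
kernel = KernelSpec(gamma=gamma)
print(f"median-heuristic RBF gamma = {gamma:.3g}")

fast = repeated_eval(ds, ModelSpec(kind="fsvm", r=0.5, kernel=kernel),
                     reps=10, base_seed=0)
full = repeated_eval(ds, ModelSpec(kind="svm", kernel=kernel),
                     reps=10, base_seed=0)
print(f"fast SVM (r=0.5): mean accuracy {fast.mean_accuracy:.4f}, "
      f"solver size {int(np.mean(fast.solver_sizes))}")
print(f"plain SVM       : mean accuracy {full.mean_accuracy:.4f}, "
      f"solver size {int(np.mean(full.solver_sizes))}")
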