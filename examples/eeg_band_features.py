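"""Extract EEG band features and show the fatigue signature.

Computes differential-entropy (DE) features per (channel, rhythm band) for
the posterior area of a simulated recording and prints the mean feature per
band for awake vs fatigue epochs.  Under fatigue the theta and alpha band
entropies rise (more band power) and beta falls — the structure the
classifier exploits.
"""

from fatiguekit import SimulationConfig, extract_eeg_features, simulate_recording

rec = simulate_recording(SimulationConfig(duration_s=64.0, fs=200.0, seed=2))
df = extract_eeg_features(rec, montage={"P": rec.by_role("EEG-P")}, kind="DE")

n_feat = sum(c not in ("epoch_start_s", "label") for c in df.columns)
print(f"{len(df)} epochs x {n_feat} DE features (11 posterior leads x 5 bands)")
print(f"{'band':>6} {'awake':>8} {'fatigue':>8}   (mean DE, nats)")
for band in ("delta", "theta", "alpha", "beta", "gamma"):
    cols = [c for c in df.columns if c.endswith(f"_{band}_DE")]
    awake = df[df.label == 0][cols].mean().mean()
    fatigue = df[df.label == 1][cols].mean().mean()
    print(f"{band:>6} {awake:>8.3f} {fatigue:>8.3f}")
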