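"""Simulate a driving-vigilance recording and label it from the EOG.

Builds a 64 s recording (first half awake, second half fatigued), separates
the vertical electrooculogram from the four forehead electrodes, detects
blinks, and prints PERCLOS — the fraction of each 8 s window the eyes are
closed — with the resulting awake/fatigue label (threshold 0.35).
"""

from fatiguekit import (
    SimulationConfig,
    compute_perclos,
    default_eog_positions,
    detect_blinks,
    separate_hv,
    simulate_recording,
)

rec = simulate_recording(SimulationConfig(duration_s=64.0, fs=200.0, seed=1))
eog = {pos: rec.get(name) for pos, name in default_eog_positions(rec).items()}
_, vertical = separate_hv(eog)
events = detect_blinks(vertical, rec.fs)
print(f"{len(events)} blinks detected in {rec.duration_s:.0f} s")

closures = [e.closure for e in events]
print(f"{'window':>10} {'PERCLOS':>8} {'label':>6}   (0 awake, 1 fatigue)")
for w in range(8):
    pw = compute_perclos(closures, (w * 8.0, (w + 1) * 8.0))
    print(f"{pw.t0:>6.0f}-{pw.t1:<3.0f} {pw.P:>8.3f} {pw.label:>6}")
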