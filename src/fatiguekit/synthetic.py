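"""Synthetic EEG/EOG recordings and feature datasets with known ground truth.

The simulator emulates the statistical structure the recognition chain relies
on, so every downstream stage is testable without a driving-study recording:

* EEG channels are sums of band-limited oscillations (filtered Gaussian
  noise) whose per-band power switches with the vigilance state.  Under
  fatigue the theta and alpha powers rise and beta falls — the classic
  drowsiness signature.
* The four forehead electrodes carry a shared frontal EEG component, a slow
  common drift, and (upper electrode) raised-cosine blink deflections.  The
  eyes count as closed while a deflection exceeds half its peak, so a blink
  of total duration 2*tau contributes exactly tau of closure: closure
  fraction = blink_rate/60 * closure_duration per state.
* A per-sample ground-truth state track and the exact closure intervals are
  attached to the recording.

All randomness flows from one seed through numpy's splittable SeedSequence,
so each signal component can be reproduced independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .fsvm import LabeledDataset
from .preprocess import BANDS, DEFAULT_EPOCH_LEN_S, bandpass
from .recording import SignalRecording, default_channels

#: Per-state band power (µV²).  Fatigue: theta/alpha up, beta down.
DEFAULT_BAND_POWER = {
    0: {"delta": 10.0, "theta": 4.0, "alpha": 5.0, "beta": 8.0, "gamma": 2.0},
    1: {"delta": 10.0, "theta": 9.0, "alpha": 11.0, "beta": 3.0, "gamma": 2.0},
}

#: Blink events per minute per state; fatigued drivers blink longer and more.
DEFAULT_BLINK_RATE = {0: 10.0, 1: 30.0}

#: Eye-closure duration per blink (s); fatigue 1.0 s * 30/min -> closure 0.5.
DEFAULT_CLOSURE_DURATION = {0: 0.2, 1: 1.0}


@dataclass
class SimulationConfig:
    """Recording simulation parameters.

    ``state_schedule`` is a list of ``(state, duration_s)`` segments; when
    omitted the recording alternates awake/fatigue in 32 s blocks over
    ``duration_s``.  ``band_power_map[state][band]`` is the EEG power in µV²
    for each rhythm band; ``blink_rate_per_state`` is in events/min and
    ``closure_duration_per_state`` in seconds per blink, so the programmed
    eye-closure fraction of a state is ``rate/60 * closure_duration``.
    """

    duration_s: float = 64.0
    fs: float = 1000.0
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S
    state_schedule: list[tuple[int, float]] | None = None
    band_power_map: dict[int, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_BAND_POWER.items()}
    )
    blink_rate_per_state: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BLINK_RATE)
    )
    closure_duration_per_state: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLOSURE_DURATION)
    )
    blink_amplitude_uv: float = 300.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.epoch_len_s <= 0:
            raise ConfigError("epoch_len_s must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for state, powers in self.band_power_map.items():
            for band, p in powers.items():
                if p < 0:
                    raise ConfigError(f"negative power for state {state} band {band}")
        for d in self.closure_duration_per_state.values():
            if d < 0:
                raise ConfigError("closure durations must be non-negative")
        for r in self.blink_rate_per_state.values():
            if r < 0:
                raise ConfigError("blink rates must be non-negative")
        self.resolved_schedule()  # validates coverage and state values

    def resolved_schedule(self) -> list[tuple[int, float]]:
        if self.state_schedule is not None:
            sched = self.state_schedule
        else:
            sched = []
            t, state = 0.0, 0
            while t < self.duration_s:
                seg = min(32.0, self.duration_s - t)
                sched.append((state, seg))
                t += seg
                state = 1 - state
        total = sum(d for _, d in sched)
        if abs(total - self.duration_s) > 1e-9:
            raise ConfigError(
                f"state schedule covers {total} s, recording lasts {self.duration_s} s"
            )
        for state, d in sched:
            if state not in (0, 1) or d < 0:
                raise ConfigError("schedule entries must be (state in {0,1}, dur >= 0)")
        return sched


def _state_track(config: SimulationConfig) -> np.ndarray:
    n = int(round(config.duration_s * config.fs))
    track = np.zeros(n, dtype=int)
    t0 = 0
    for state, dur in config.resolved_schedule():
        n_seg = int(round(dur * config.fs))
        track[t0 : t0 + n_seg] = state
        t0 += n_seg
    return track


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = bandpass(rng.standard_normal(n), fs, lo, hi)
    sd = x.std()
    return x / sd if sd > 0 else x


def _eeg_channel(
    rng: np.random.Generator, config: SimulationConfig, track: np.ndarray
) -> np.ndarray:
    n = track.size
    out = np.zeros(n)
    for band, (lo, hi) in BANDS.items():
        powers = np.array(
            [config.band_power_map.get(s, {}).get(band, 0.0) for s in (0, 1)]
        )
        # bands above Nyquist are dropped at low simulation rates
        hi = min(hi, 0.45 * config.fs)
        if np.all(powers == 0) or hi <= lo:
            continue
        out += np.sqrt(powers[track]) * _band_noise(rng, n, config.fs, lo, hi)
    if config.noise_sd > 0:
        out += config.noise_sd * rng.standard_normal(n)
    return out


def _blink_times(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[float, float]]:
    """Blink peak times with per-blink closure duration, per the schedule.

    Blinks are placed quasi-periodically (interval 60/rate, +-5% jitter) so
    the realized closure fraction of every epoch tracks the programmed one.
    """
    events: list[tuple[float, float]] = []
    t0 = 0.0
    for state, dur in config.resolved_schedule():
        rate = config.blink_rate_per_state.get(state, 0.0)
        tau = config.closure_duration_per_state.get(state, 0.0)
        if rate > 0 and tau > 0:
            interval = 60.0 / rate
            k = 0
            while (k + 0.5) * interval < dur:
                peak = t0 + (k + 0.5) * interval + rng.uniform(-0.05, 0.05) * interval
                # clamp so the full raised-cosine support stays in the segment
                if dur >= 2 * tau:
                    peak = min(max(peak, t0 + tau), t0 + dur - tau)
                    events.append((peak, tau))
                k += 1
        t0 += dur
    return events


def _render_blinks(
    events: list[tuple[float, float]], n: int, fs: float, amplitude: float
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Raised-cosine deflections; above half-peak for exactly the closure span."""
    b = np.zeros(n)
    closures: list[tuple[float, float]] = []
    for peak, tau in events:
        width = 2.0 * tau  # half-peak width == tau
        i0 = int(round((peak - width / 2) * fs))
        i1 = int(round((peak + width / 2) * fs))
        idx = np.arange(max(i0, 0), min(i1, n))
        if idx.size == 0:
            continue
        phase = (idx / fs - (peak - width / 2)) / width
        b[idx] += amplitude * 0.5 * (1 - np.cos(2 * np.pi * phase))
        closures.append((peak - tau / 2, peak + tau / 2))
    return b, closures


def simulate_recording(config: SimulationConfig) -> SignalRecording:
    """Generate a 21-channel recording (11 P, 6 T, 4 forehead EOG).

    EEG channels carry state-dependent rhythm-band power; the forehead
    channels share a frontal EEG component and slow drift, with blink
    deflections on the upper electrode and a slow-eye-movement dipole on the
    left/right pair.  The returned recording includes the ground-truth state
    track and the exact programmed closure intervals.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(4)
    rng_eeg = np.random.default_rng(keys[0])
    rng_blink = np.random.default_rng(keys[1])
    rng_front = np.random.default_rng(keys[2])
    rng_noise = np.random.default_rng(keys[3])

    track = _state_track(config)
    n = track.size
    channels = default_channels()

    data = np.zeros((len(channels), n))
    roles = [role for _, role in channels]
    for i, role in enumerate(roles):
        if role in ("EEG-P", "EEG-T", "EEG-F"):
            data[i] = _eeg_channel(rng_eeg, config, track)

    # forehead electrodes: shared frontal EEG + drift, blink on upper,
    # horizontal slow-eye-movement dipole on left/right
    eog_rows = [i for i, role in enumerate(roles) if role == "EOG"]
    closures: list[tuple[float, float]] = []
    if eog_rows:
        frontal = 0.5 * _eeg_channel(rng_front, config, track)
        drift = np.zeros(n)
        sem = np.zeros(n)
        if config.noise_sd > 0 and n > int(config.fs):
            drift = 20.0 * _band_noise(rng_front, n, config.fs, 0.05, 0.3)
            sem = 15.0 * _band_noise(rng_front, n, config.fs, 0.1, 0.4)
        blink_wave = np.zeros(n)
        events = _blink_times(rng_blink, config)
        if events and config.blink_amplitude_uv > 0:
            blink_wave, closures = _render_blinks(
                events, n, config.fs, config.blink_amplitude_uv
            )
        for row, pos in zip(eog_rows, ("left", "right", "upper", "lower")):
            x = frontal + drift
            if pos == "upper":
                x = x + blink_wave
            elif pos == "left":
                x = x + sem
            elif pos == "right":
                x = x - sem
            if config.noise_sd > 0:
                x = x + config.noise_sd * rng_noise.standard_normal(n)
            data[row] = x

    return SignalRecording(
        samples=data,
        fs=config.fs,
        channels=channels,
        state_track=track,
        closure_intervals=closures,
    )


def simulate_feature_dataset(
    n_pos: int,
    n_neg: int,
    dim: int = 4,
    separation: float = 30.0,
    seed: int = 0,
    scale: float = 10.0,
) -> LabeledDataset:
    """Two spherical Gaussian clouds with class-mean distance ``separation``.

    Positives (label 1) sit at +separation/2 along the first axis, negatives
    at -separation/2; both have isotropic standard deviation ``scale``.
    Rows are positives first, then negatives.

    The default scale of 10 puts typical squared point-to-point distances on
    the order of 1/gamma for the default RBF kernel (gamma = 0.001, length
    scale ~32), i.e. the regime the kernel parameter is designed for —
    matching the magnitude of real band-power/entropy feature vectors.
    """
    if n_pos < 1 or n_neg < 1:
        raise ConfigError("need at least one point per class")
    if dim < 1:
        raise ConfigError("dim must be >= 1")
    if separation < 0:
        raise ConfigError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    mu = np.zeros(dim)
    mu[0] = separation / 2.0
    X_pos = rng.normal(size=(n_pos, dim)) * scale + mu
    X_neg = rng.normal(size=(n_neg, dim)) * scale - mu
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return LabeledDataset(X=X, y=y)
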