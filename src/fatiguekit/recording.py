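"""Multichannel biosignal recording container and montage helpers.

A :class:`SignalRecording` holds per-channel time series in microvolts together
with the sampling rate, a channel table of ``(name, role)`` pairs, and an
optional per-sample ground-truth vigilance track (0 awake, 1 fatigue).

Channel roles
-------------
``EEG-P``   posterior/occipital scalp electrodes
``EEG-T``   temporal scalp electrodes
``EEG-F``   dedicated frontal scalp electrodes
``EOG``     forehead electrodes around the eyes (also carry frontal EEG)

The default acquisition layout has 21 channels: 11 posterior, 6 temporal and
4 forehead electrodes.  The frontal EEG area is derived from the forehead
electrodes, so an area montage may map ``EOG``-role channels to area ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_ROLES = ("EEG-P", "EEG-T", "EEG-F", "EOG")

#: EOG electrode positions required by the horizontal/vertical separation rule.
EOG_POSITIONS = ("left", "right", "upper", "lower")


class RecordingError(ValueError):
    """Invalid recording structure or malformed recording file."""


@dataclass
class SignalRecording:
    """Multichannel time series in microvolts.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz (default 1000).
    channels
        ``(name, role)`` per channel, role one of :data:`CHANNEL_ROLES`.
    state_track
        Optional per-sample vigilance state, 0 (awake) or 1 (fatigue).
    closure_intervals
        Optional ground-truth eye-closure intervals ``(start_s, end_s)``;
        populated by the simulator, never read from files.
    """

    samples: np.ndarray
    fs: float
    channels: list[tuple[str, str]]
    state_track: np.ndarray | None = None
    closure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise RecordingError("samples must be a (n_channels, n_samples) array")
        if self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != self.samples.shape[0]:
            raise RecordingError(
                f"{len(self.channels)} channel entries for "
                f"{self.samples.shape[0]} signal rows"
            )
        for name, role in self.channels:
            if role not in CHANNEL_ROLES:
                raise RecordingError(f"unknown role {role!r} for channel {name!r}")
        if self.state_track is not None:
            self.state_track = np.asarray(self.state_track, dtype=int)
            if self.state_track.shape != (self.samples.shape[1],):
                raise RecordingError("state_track length must equal sample length")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels]

    def channel_index(self, name: str) -> int:
        for i, (ch, _) in enumerate(self.channels):
            if ch == name:
                return i
        raise RecordingError(f"no channel named {name!r}")

    def by_role(self, role: str) -> list[str]:
        """Names of all channels with the given role."""
        return [name for name, r in self.channels if r == role]

    def get(self, name: str) -> np.ndarray:
        return self.samples[self.channel_index(name)]


def default_channels() -> list[tuple[str, str]]:
    """The 21-channel acquisition layout: 11 P + 6 T + 4 forehead EOG."""
    chans = [(f"P{i+1}", "EEG-P") for i in range(11)]
    chans += [(f"T{i+1}", "EEG-T") for i in range(6)]
    chans += [(f"EOG-{p}", "EOG") for p in ("L", "R", "U", "D")]
    return chans


def default_montage(rec: SignalRecording) -> dict[str, list[str]]:
    """Map EEG areas P/T/F to channel names for feature extraction.

    P and T areas come from their scalp electrodes; the frontal area F is
    read from dedicated ``EEG-F`` channels when present, otherwise from the
    four forehead electrodes (the frontal EEG is carried by the forehead
    leads in the default layout).
    """
    montage = {"P": rec.by_role("EEG-P"), "T": rec.by_role("EEG-T")}
    f = rec.by_role("EEG-F") or rec.by_role("EOG")
    montage["F"] = f
    return {area: names for area, names in montage.items() if names}


def default_eog_positions(rec: SignalRecording) -> dict[str, str]:
    """Map left/right/upper/lower positions to the default EOG channel names."""
    eog = rec.by_role("EOG")
    if len(eog) != 4:
        raise RecordingError(f"need exactly 4 EOG channels, found {len(eog)}")
    return dict(zip(EOG_POSITIONS, eog))
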