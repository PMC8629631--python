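"""Epoching and rhythm-band decomposition of recordings.

EEG analysis here works on the five conventional rhythm bands; the band edges
are the standard clinical definitions (Hz):

====== ========
delta  1 – 4
theta  4 – 8
alpha  8 – 13
beta   13 – 30
gamma  30 – 50
====== ========

Band-pass filtering is zero-phase (forward-backward 4th-order Butterworth per
pass), so band features carry no phase distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .recording import SignalRecording

log = logging.getLogger(__name__)

#: Rhythm band edges in Hz, in canonical order.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

BAND_ORDER = tuple(BANDS)

#: Default analysis window length in seconds.
DEFAULT_EPOCH_LEN_S = 8.0


@dataclass
class Epoch:
    """One analysis window cut from a recording."""

    samples: np.ndarray  # (n_channels, n) microvolts
    channels: list[tuple[str, str]]
    start_s: float
    fs: float
    state: int | None = None  # majority ground-truth state, if known

    @property
    def len_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class BandSegment:
    """A single channel of one epoch restricted to one rhythm band."""

    band_name: str
    channel: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.band_name not in BANDS:
            raise ConfigError(f"unknown band {self.band_name!r}")


def bandpass(samples: np.ndarray, fs: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Zero-phase band-pass filter, same length as the input.

    Raises :class:`ConfigError` if the band does not satisfy
    ``0 < low < high < fs/2``.
    """
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ConfigError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={fs / 2}) Hz"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def epoch_signal(
    rec: SignalRecording,
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    stride_s: float | None = None,
) -> list[Epoch]:
    """Cut a recording into fixed-length windows.

    Windows start at multiples of ``stride_s`` (default: non-overlapping,
    stride = length); a trailing partial window is dropped.  When the
    recording carries a ground-truth state track, each epoch is labeled with
    the majority state in its window; ties go to fatigue (1), the
    safety-conservative call.
    """
    if epoch_len_s <= 0:
        raise ConfigError("epoch length must be positive")
    stride_s = epoch_len_s if stride_s is None else stride_s
    if stride_s <= 0:
        raise ConfigError("stride must be positive")
    n_epoch = int(round(epoch_len_s * rec.fs))
    n_stride = int(round(stride_s * rec.fs))
    epochs: list[Epoch] = []
    start = 0
    while start + n_epoch <= rec.n_samples:
        seg = rec.samples[:, start : start + n_epoch]
        state = None
        if rec.state_track is not None:
            frac_fatigue = rec.state_track[start : start + n_epoch].mean()
            state = 1 if frac_fatigue >= 0.5 else 0
        epochs.append(
            Epoch(
                samples=seg,
                channels=list(rec.channels),
                start_s=start / rec.fs,
                fs=rec.fs,
                state=state,
            )
        )
        start += n_stride
    if not epochs:
        log.warning(
            "epoch length %.3g s exceeds recording duration %.3g s; no epochs",
            epoch_len_s,
            rec.duration_s,
        )
    return epochs


def split_bands(
    epoch: Epoch,
    bands: dict[str, tuple[float, float]] | None = None,
    channel_names: list[str] | None = None,
) -> list[BandSegment]:
    """Decompose an epoch into per-(channel, band) segments.

    By default every EEG-role channel is decomposed into the five rhythm
    bands; pass ``channel_names`` to restrict to a montage area.
    """
    if epoch.samples.size == 0:
        raise ConfigError("empty epoch")
    bands = BANDS if bands is None else bands
    if channel_names is None:
        channel_names = [n for n, role in epoch.channels if role.startswith("EEG")]
    name_to_idx = {n: i for i, (n, _) in enumerate(epoch.channels)}
    segments: list[BandSegment] = []
    for ch in channel_names:
        x = epoch.samples[name_to_idx[ch]]
        for band_name, (lo, hi) in bands.items():
            segments.append(
                BandSegment(
                    band_name=band_name,
                    channel=ch,
                    samples=bandpass(x, epoch.fs, lo, hi),
                    fs=epoch.fs,
                )
            )
    return segments
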