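"""EEG band features: differential entropy, band PSD, and LDS smoothing.

Differential entropy (DE) of a continuous random variable is
``h(X) = -∫ f(x) ln f(x) dx``.  An EEG band-limited segment is modeled as
Gaussian N(mu, sigma^2), for which the integral has the closed form

    h = 1/2 * ln(2 * pi * e * sigma^2)        [nats]

so the DE feature of a band segment is a monotone function of the band
power.  The natural logarithm is used throughout; sigma^2 is the unbiased
(n-1) sample variance.

The PSD feature is the mean periodogram power within the segment's band
(µV²/Hz, density scaling), computed from a single Hann-windowed Fourier
transform of the segment by default; Welch-style sub-window averaging is
available via ``nperseg``.

Feature trajectories across epochs are optionally smoothed with a
linear-dynamic-system smoother: a local-level state-space model (random-walk
state, additive observation noise) run through a Kalman filter and
Rauch-Tung-Striebel backward pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, DataError
from .preprocess import BANDS, BAND_ORDER, BandSegment, Epoch, bandpass, epoch_signal
from .recording import SignalRecording, default_montage

log = logging.getLogger(__name__)

FEATURE_KINDS = ("PSD", "DE")


@dataclass
class GaussianBandSummary:
    """Gaussian fit of a band segment: mean, variance, sample count."""

    mu: float
    sigma2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError("need at least 2 samples")
        if self.sigma2 < 0:
            raise DataError("variance must be non-negative")


def fit_gaussian(segment: BandSegment) -> GaussianBandSummary:
    x = np.asarray(segment.samples, dtype=float)
    if x.size < 2:
        raise DataError("segment must have at least 2 samples")
    return GaussianBandSummary(mu=float(x.mean()), sigma2=float(x.var(ddof=1)), n=x.size)


def de_from_variance(sigma2: float) -> float:
    """Closed-form Gaussian differential entropy, 1/2 ln(2 pi e sigma^2), nats."""
    if sigma2 < 0:
        raise DataError("variance must be non-negative")
    if sigma2 == 0:
        log.warning("zero-variance segment: differential entropy is -inf")
        return -math.inf
    return 0.5 * math.log(2.0 * math.pi * math.e * sigma2)


def de_feature(segment: BandSegment) -> float:
    """Differential entropy (nats) of a band segment under the Gaussian model."""
    return de_from_variance(fit_gaussian(segment).sigma2)


def band_psd(
    samples: np.ndarray,
    fs: float,
    band: tuple[float, float],
    nperseg: int | None = None,
    window: str = "hann",
) -> float:
    """Mean periodogram power density (µV²/Hz) within ``band``.

    ``nperseg=None`` uses a single full-length segment (one Fourier frame);
    a smaller value averages Welch-style across sub-windows.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DataError("segment must have at least 2 samples")
    lo, hi = band
    if nperseg is None:
        nperseg = x.size
    freqs, pxx = sps.welch(
        x, fs=fs, window=window, nperseg=min(nperseg, x.size), scaling="density"
    )
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        # fewer bins than bands can resolve: take nearest bin
        mask = np.abs(freqs - 0.5 * (lo + hi)).argmin()
        return float(pxx[mask])
    return float(pxx[mask].mean())


def psd_feature(segment: BandSegment, nperseg: int | None = None) -> float:
    """PSD feature of a band segment: mean power density in its own band."""
    return band_psd(segment.samples, segment.fs, BANDS[segment.band_name], nperseg)


def lds_smooth(
    series: np.ndarray, process_var: float = 0.1, obs_var: float = 1.0
) -> np.ndarray:
    """Fixed-interval smoothing under a local-level linear dynamic system.

    Model: x_t = x_{t-1} + w_t, w_t ~ N(0, process_var);
           y_t = x_t + v_t,     v_t ~ N(0, obs_var).
    Forward Kalman filter initialized at the first observation, then a
    Rauch-Tung-Striebel backward pass.  Same length as the input.
    """
    y = np.asarray(series, dtype=float)
    if y.size == 0:
        raise DataError("series must be non-empty")
    if not np.all(np.isfinite(y)):
        raise DataError("series contains non-finite values")
    if process_var <= 0 or obs_var < 0:
        raise ConfigError("variances must be positive (obs_var may be 0)")
    n = y.size
    xf = np.empty(n)  # filtered mean
    pf = np.empty(n)  # filtered variance
    xp = np.empty(n)  # one-step predicted mean
    pp = np.empty(n)
    xf[0], pf[0] = y[0], obs_var
    xp[0], pp[0] = y[0], obs_var
    for t in range(1, n):
        xp[t] = xf[t - 1]
        pp[t] = pf[t - 1] + process_var
        k = pp[t] / (pp[t] + obs_var) if (pp[t] + obs_var) > 0 else 1.0
        xf[t] = xp[t] + k * (y[t] - xp[t])
        pf[t] = (1.0 - k) * pp[t]
    xs = xf.copy()
    for t in range(n - 2, -1, -1):
        g = pf[t] / pp[t + 1] if pp[t + 1] > 0 else 0.0
        xs[t] = xf[t] + g * (xs[t + 1] - xp[t + 1])
    return xs


def feature_column_name(area: str, channel: str, band: str, kind: str) -> str:
    return f"{area}_{channel}_{band}_{kind}"


def extract_eeg_features(
    source: SignalRecording | list[Epoch],
    montage: dict[str, list[str]] | None = None,
    kind: str = "DE",
    smooth: bool = False,
    epoch_len_s: float | None = None,
    stride_s: float | None = None,
    process_var: float = 0.1,
    obs_var: float = 1.0,
    nperseg: int | None = None,
) -> pd.DataFrame:
    """Per-epoch (channel, band) feature table for the montage's EEG areas.

    Each epoch yields one value per (channel, band) pair per area — e.g. 55
    for an 11-lead area, 30 for 6 leads, 20 for 4 leads, five rhythm bands
    each.  Column layout is channel-major: ``<area>_<channel>_<band>_<kind>``.
    ``smooth=True`` applies the LDS smoother independently to each feature
    dimension across epochs.  Returns a DataFrame with ``epoch_start_s`` and
    ``label`` (the epoch's majority ground-truth state, -1 if unknown).
    """
    if kind not in FEATURE_KINDS:
        raise ConfigError(f"kind must be one of {FEATURE_KINDS}, got {kind!r}")
    if isinstance(source, SignalRecording):
        kwargs = {}
        if epoch_len_s is not None:
            kwargs["epoch_len_s"] = epoch_len_s
        epochs = epoch_signal(source, stride_s=stride_s, **kwargs)
        if montage is None:
            montage = default_montage(source)
    else:
        epochs = source
        if montage is None:
            raise ConfigError("montage is required when passing epochs directly")
    if not epochs:
        raise DataError("no epochs to extract features from")

    known = {name for e in [epochs[0]] for name, _ in e.channels}
    for area, names in montage.items():
        missing = [n for n in names if n not in known]
        if missing:
            raise ConfigError(f"montage area {area!r} names unknown channels {missing}")

    columns = [
        feature_column_name(area, ch, band, kind)
        for area, names in montage.items()
        for ch in names
        for band in BAND_ORDER
    ]
    rows = np.empty((len(epochs), len(columns)))
    for i, ep in enumerate(epochs):
        name_to_idx = {n: j for j, (n, _) in enumerate(ep.channels)}
        j = 0
        for area, names in montage.items():
            for ch in names:
                x = ep.samples[name_to_idx[ch]]
                for band in BAND_ORDER:
                    lo, hi = BANDS[band]
                    if kind == "DE":
                        xb = bandpass(x, ep.fs, lo, hi)
                        rows[i, j] = de_from_variance(float(np.var(xb, ddof=1)))
                    else:
                        rows[i, j] = band_psd(x, ep.fs, (lo, hi), nperseg)
                    j += 1
    if smooth and len(epochs) > 1:
        for j in range(rows.shape[1]):
            rows[:, j] = lds_smooth(rows[:, j], process_var, obs_var)

    df = pd.DataFrame(rows, columns=columns)
    df.insert(0, "label", [(-1 if ep.state is None else ep.state) for ep in epochs])
    df.insert(0, "epoch_start_s", [ep.start_s for ep in epochs])
    return df
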