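"""EOG processing: H/V separation, blink detection, PERCLOS and fatigue labels.

The four forehead electrodes (left, right, upper, lower) are combined into a
horizontal and a vertical electrooculogram either by the subtraction rule

    vertical = upper - lower,    horizontal = left - right

or by blind source separation (FastICA), where the two retained components
are those best correlated with the subtraction-rule traces and are
sign/scale-aligned to them.  A mixed variant uses the BSS vertical with the
subtraction horizontal.

Blinks are detected on the vertical trace by a continuous wavelet transform
(Mexican-hat family at scales spanning 0.1-0.5 s); coefficient peaks above
3x the median absolute deviation become events, and the eye counts as closed
while the deflection exceeds half the event's peak amplitude.

PERCLOS — the fraction of a window the eyes are closed —

    P = eye_closing_time / total_time

drives the binary vigilance label: P < 0.35 is awake (0), otherwise fatigue
(1).  P = 0.35 exactly is assigned to fatigue, the safety-conservative call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .errors import ConfigError, DataError
from .recording import EOG_POSITIONS

log = logging.getLogger(__name__)

PERCLOS_THRESHOLD = 0.35

#: Blink half-duration range the CWT scales span, in seconds.
BLINK_SCALE_RANGE_S = (0.1, 0.5)

#: Separation variants for (horizontal, vertical) derivation.
VARIANTS = ("minus", "ica", "icav_minh")


@dataclass
class BlinkEvent:
    """One detected blink with its eye-closure span."""

    start_s: float
    end_s: float
    peak_amplitude: float
    close_s: float
    open_s: float

    def __post_init__(self) -> None:
        if not (self.start_s <= self.close_s < self.open_s <= self.end_s):
            raise DataError("closure interval must nest inside the event")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def closure(self) -> tuple[float, float]:
        return (self.close_s, self.open_s)


@dataclass
class PerclosWindow:
    """PERCLOS over one window with its Table-rule label."""

    t0: float
    t1: float
    eye_closing_time: float
    P: float
    label: int

    @property
    def total_time(self) -> float:
        return self.t1 - self.t0


def _positions(eog: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    missing = [p for p in EOG_POSITIONS if p not in eog]
    if missing:
        raise ConfigError(f"EOG channels missing position declarations: {missing}")
    return {p: np.asarray(eog[p], dtype=float) for p in EOG_POSITIONS}


def separate_hv(eog: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Subtraction rule: horizontal = left - right, vertical = upper - lower.

    ``eog`` maps the positions ``left/right/upper/lower`` to channel series.
    """
    ch = _positions(eog)
    return ch["left"] - ch["right"], ch["upper"] - ch["lower"]


def bss_separate(
    eog: dict[str, np.ndarray], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Blind source separation of the EOG channels into (horizontal, vertical).

    FastICA components are matched to the subtraction-rule traces by absolute
    correlation, then sign- and scale-aligned by least squares.  Degenerate
    inputs (rank-deficient, non-convergent) fall back to the subtraction rule
    with a warning.
    """
    h_ref, v_ref = separate_hv(eog)
    X = np.vstack([np.asarray(x, dtype=float) for x in eog.values()]).T
    if X.shape[0] <= X.shape[1]:
        raise DataError("need more samples than channels for source separation")

    def _fallback(reason: str) -> tuple[np.ndarray, np.ndarray]:
        log.warning("BSS separation failed (%s); using subtraction rule", reason)
        return h_ref, v_ref

    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(np.cov(Xc.T)) < 2:
        return _fallback("input is rank-deficient")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            ica = FastICA(
                n_components=min(X.shape[1], 4),
                random_state=np.random.RandomState(seed),
                whiten="unit-variance",
                max_iter=500,
            )
            S = ica.fit_transform(X)
    except Exception as e:  # convergence warning or numerical failure
        return _fallback(str(e))

    def _match(ref: np.ndarray) -> np.ndarray:
        refc = ref - ref.mean()
        denom = np.linalg.norm(refc)
        best, best_c = None, -1.0
        for j in range(S.shape[1]):
            s = S[:, j] - S[:, j].mean()
            ns = np.linalg.norm(s)
            if ns == 0 or denom == 0:
                continue
            c = abs(float(s @ refc) / (ns * denom))
            if c > best_c:
                best, best_c = j, c
        if best is None:
            raise DataError("no usable component")
        comp = S[:, best]
        # least-squares scale (carries the sign alignment)
        a = float(comp @ refc) / float(comp @ comp)
        return a * comp + ref.mean()

    try:
        return _match(h_ref), _match(v_ref)
    except DataError as e:
        return _fallback(str(e))


def detect_blinks(
    vertical: np.ndarray,
    fs: float,
    threshold_mads: float = 3.0,
    min_separation_s: float = 0.2,
) -> list[BlinkEvent]:
    """Blink events from the vertical EOG via Mexican-hat CWT peak detection.

    Peaks in the maximal CWT response across blink scales that exceed
    ``threshold_mads`` times the median absolute deviation of the
    coefficients become events.  Around each peak, the event extends while
    the deflection stays above 10% of its peak and the closure interval while
    it stays above half-peak.  Overlapping events are merged; events are
    returned sorted and non-overlapping.
    """
    v = np.asarray(vertical, dtype=float)
    if v.size < fs:
        raise DataError("need at least 1 s of signal")
    lo, hi = BLINK_SCALE_RANGE_S
    # mexh central width ~ scale samples either side of the peak
    scales = np.linspace(lo * fs / 2, hi * fs / 2, 8)
    coeffs, _ = pywt.cwt(v, scales, "mexh")
    response = np.abs(coeffs).max(axis=0)
    mad = np.median(np.abs(response - np.median(response)))
    thr = threshold_mads * mad if mad > 0 else 0.0
    if thr == 0.0 and response.max() == 0.0:
        return []
    peaks, _ = sps.find_peaks(
        response, height=max(thr, 1e-12), distance=max(int(min_separation_s * fs), 1)
    )
    raw: list[tuple[int, int, float, int, int]] = []
    for p in peaks:
        # refine the apex on the signal itself inside the wavelet support
        half = int(hi * fs)
        w0, w1 = max(p - half, 0), min(p + half + 1, v.size)
        apex = w0 + int(np.argmax(v[w0:w1]))
        peak_amp = v[apex]
        if peak_amp <= 0:
            continue
        lo_thr, half_thr = 0.1 * peak_amp, 0.5 * peak_amp

        def _extent(level: float) -> tuple[int, int]:
            i = apex
            while i > 0 and v[i - 1] >= level:
                i -= 1
            j = apex
            while j < v.size - 1 and v[j + 1] >= level:
                j += 1
            return i, j

        e0, e1 = _extent(lo_thr)
        c0, c1 = _extent(half_thr)
        raw.append((e0, e1, peak_amp, c0, c1))

    raw.sort()
    merged: list[list] = []
    for e0, e1, amp, c0, c1 in raw:
        if merged and e0 <= merged[-1][1]:
            m = merged[-1]
            m[1] = max(m[1], e1)
            if amp > m[2]:
                m[2], m[3], m[4] = amp, c0, c1
        else:
            merged.append([e0, e1, amp, c0, c1])

    return [
        BlinkEvent(
            start_s=e0 / fs,
            end_s=(e1 + 1) / fs,
            peak_amplitude=amp,
            close_s=c0 / fs,
            open_s=(c1 + 1) / fs,
        )
        for e0, e1, amp, c0, c1 in merged
    ]


def compute_perclos(
    closures: list[tuple[float, float]], window: tuple[float, float]
) -> PerclosWindow:
    """P = eye_closing_time / total_time over the window; closures clipped."""
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("window must have positive length")
    closed = 0.0
    for c0, c1 in closures:
        closed += max(0.0, min(c1, t1) - max(c0, t0))
    P = closed / (t1 - t0)
    P = min(P, 1.0)
    return PerclosWindow(
        t0=t0, t1=t1, eye_closing_time=closed, P=P, label=label_from_perclos(P)
    )


def label_from_perclos(P: float) -> int:
    """0 (awake) for P < 0.35, 1 (fatigue) for P >= 0.35."""
    if not (0.0 <= P <= 1.0):
        raise DataError(f"PERCLOS must lie in [0, 1], got {P}")
    return 0 if P < PERCLOS_THRESHOLD else 1


def extract_eog_features(
    h: np.ndarray,
    v: np.ndarray,
    fs: float,
    events: list[BlinkEvent] | None = None,
    window_len_s: float = 8.0,
    variant: str = "minus",
) -> pd.DataFrame:
    """Per-window EOG feature table with PERCLOS labels.

    Features per window: blink rate (/min), mean and max blink duration (s),
    mean blink peak amplitude (µV), PERCLOS, and the slow-eye-movement
    proportion (fraction of horizontal power below 0.5 Hz).  ``variant``
    records which separation produced (h, v): ``minus`` (subtraction),
    ``ica`` (BSS both) or ``icav_minh`` (BSS vertical, subtraction
    horizontal).
    """
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}")
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if h.shape != v.shape:
        raise DataError("horizontal and vertical series must have equal length")
    if window_len_s <= 0:
        raise ConfigError("window length must be positive")
    if events is None:
        events = detect_blinks(v, fs)

    n_win = int(v.size / (window_len_s * fs))
    rows = []
    for w in range(max(n_win, 0)):
        t0, t1 = w * window_len_s, (w + 1) * window_len_s
        in_win = [e for e in events if t0 <= 0.5 * (e.start_s + e.end_s) < t1]
        closures = [e.closure for e in events]
        pw = compute_perclos(closures, (t0, t1))
        durs = [e.duration_s for e in in_win]
        amps = [e.peak_amplitude for e in in_win]
        i0, i1 = int(t0 * fs), int(t1 * fs)
        hw = h[i0:i1]
        if np.allclose(hw, hw[0] if hw.size else 0.0):
            sem_prop = 0.0
        else:
            freqs, pxx = sps.welch(hw, fs=fs, nperseg=hw.size, scaling="density")
            total_power = float(np.trapezoid(pxx, freqs))
            low_power = float(np.trapezoid(pxx[freqs <= 0.5], freqs[freqs <= 0.5]))
            sem_prop = low_power / total_power if total_power > 0 else 0.0
        rows.append(
            {
                "window_start_s": t0,
                "blink_rate": len(in_win) * 60.0 / window_len_s,
                "mean_dur": float(np.mean(durs)) if durs else 0.0,
                "max_dur": float(np.max(durs)) if durs else 0.0,
                "mean_amp": float(np.mean(amps)) if amps else 0.0,
                "perclos": pw.P,
                "sem_prop": sem_prop,
                "label": pw.label,
                "variant": variant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "window_start_s",
            "blink_rate",
            "mean_dur",
            "max_dur",
            "mean_amp",
            "perclos",
            "sem_prop",
            "label",
            "variant",
        ],
    )
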