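"""Reading and writing recordings, feature tables and simulation configs.

Recording formats
-----------------
EDF
    European Data Format, the standard interchange format for EEG.  A
    minimal codec is implemented here: 16-bit samples, one header record
    plus per-signal headers.  Channel roles are encoded in the EDF label as
    ``"<role> <name>"`` and the ground-truth state track (when present) is
    stored as an extra signal labeled ``STATE track``.  Round-trips are exact
    up to the 16-bit quantization of the physical range.
CSV
    One header row ``time,<ch1>,<ch2>,...`` where each channel column is
    ``<name>:<role>``; values are seconds and microvolts.  An optional
    trailing ``state`` column carries the ground-truth track.  Lossless for
    float64 up to the printed precision (17 significant digits).

Feature datasets are CSV with columns ``label,f1..fD``.  Simulation configs
are flat ``key = value`` files with dotted keys mirroring
:class:`~fatiguekit.synthetic.SimulationConfig`.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .fsvm import LabeledDataset
from .recording import CHANNEL_ROLES, SignalRecording
from .synthetic import SimulationConfig

_STATE_LABEL = "STATE track"
_DIG_MIN, _DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    for p in range(width - 2, -1, -1):
        s = f"{x:.{p}f}"
        if len(s) <= width:
            return s
    raise DataError(f"cannot format {x} in {width} chars")


def _write_edf(rec: SignalRecording, path: Path) -> None:
    n = rec.n_samples
    fs = rec.fs
    # 1-second records when fs is integral and divides the length; otherwise
    # a single record spanning the whole recording.
    if abs(fs - round(fs)) < 1e-9 and n % int(round(fs)) == 0:
        spr = int(round(fs))  # samples per record per signal
        n_records = n // spr
        rec_dur = 1.0
    else:
        spr = n
        n_records = 1
        rec_dur = n / fs

    signals = [(f"{role} {name}"[:16], rec.samples[i], "uV")
               for i, (name, role) in enumerate(rec.channels)]
    if rec.state_track is not None:
        signals.append((_STATE_LABEL, rec.state_track.astype(float), ""))
    ns = len(signals)

    header = _io.BytesIO()
    header.write(_ascii_field("0", 8))
    header.write(_ascii_field("X", 80))
    header.write(_ascii_field("fatiguekit synthetic recording", 80))
    header.write(_ascii_field("01.01.00", 8))
    header.write(_ascii_field("00.00.00", 8))
    header.write(_ascii_field(256 * (ns + 1), 8))
    header.write(_ascii_field("", 44))
    header.write(_ascii_field(n_records, 8))
    header.write(_ascii_field(_fmt_float(rec_dur), 8))
    header.write(_ascii_field(ns, 4))

    phys = []
    for _, x, _ in signals:
        lo, hi = float(np.min(x)), float(np.max(x))
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise DataError("non-finite samples cannot be written to EDF")
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        phys.append((lo, hi))

    for col, width in (
        ([label for label, _, _ in signals], 16),
        (["" for _ in signals], 80),
        ([dim for _, _, dim in signals], 8),
        ([_fmt_float(lo) for lo, _ in phys], 8),
        ([_fmt_float(hi) for _, hi in phys], 8),
        ([_DIG_MIN for _ in signals], 8),
        ([_DIG_MAX for _ in signals], 8),
        (["" for _ in signals], 80),
        ([spr for _ in signals], 8),
        (["" for _ in signals], 32),
    ):
        for v in col:
            header.write(_ascii_field(v, width))

    digital = []
    for (_, x, _), (lo, hi) in zip(signals, phys):
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.rint((np.asarray(x, dtype=float) - lo) * scale + _DIG_MIN)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> SignalRecording:
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise DataError(f"{path}: truncated EDF header")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(fld(236, 8))
        rec_dur = float(fld(244, 8))
        ns = int(fld(252, 4))
        hoff = 256
        if len(raw) < 256 * (ns + 1):
            raise DataError(f"{path}: truncated EDF signal headers")
        labels = [fld(hoff + 16 * i, 16) for i in range(ns)]
        base = hoff + ns * (16 + 80 + 8)
        pmin = [float(fld(base + 8 * i, 8)) for i in range(ns)]
        base += ns * 8
        pmax = [float(fld(base + 8 * i, 8)) for i in range(ns)]
        base += ns * 8
        dmin = [int(fld(base + 8 * i, 8)) for i in range(ns)]
        base += ns * 8
        dmax = [int(fld(base + 8 * i, 8)) for i in range(ns)]
        base += ns * 8 + ns * 80
        spr = [int(fld(base + 8 * i, 8)) for i in range(ns)]
    except ValueError as e:
        raise DataError(f"{path}: malformed EDF header field: {e}") from None

    data_off = 256 * (ns + 1)
    per_record = sum(spr)
    body = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if body.size < per_record * n_records:
        raise DataError(f"{path}: EDF data section shorter than header promises")
    body = body[: per_record * n_records].reshape(n_records, per_record)

    series = []
    pos = 0
    for i in range(ns):
        d = body[:, pos : pos + spr[i]].reshape(-1).astype(float)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        series.append((d - dmin[i]) * scale + pmin[i])
        pos += spr[i]

    channels: list[tuple[str, str]] = []
    rows = []
    state = None
    for label, x in zip(labels, series):
        if label == _STATE_LABEL:
            state = np.rint(x).astype(int)
            continue
        parts = label.split(None, 1)
        if len(parts) != 2 or parts[0] not in CHANNEL_ROLES:
            raise DataError(
                f"{path}: signal label {label!r} does not encode a channel role"
            )
        role, name = parts
        channels.append((name, role))
        rows.append(x)
    fs = spr[0] / rec_dur
    return SignalRecording(
        samples=np.vstack(rows), fs=fs, channels=channels, state_track=state
    )


# ---------------------------------------------------------------------------
# CSV recording dialect
# ---------------------------------------------------------------------------

def _write_csv(rec: SignalRecording, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    cols = {"time": t}
    for (name, role), row in zip(rec.channels, rec.samples):
        cols[f"{name}:{role}"] = row
    if rec.state_track is not None:
        cols["state"] = rec.state_track
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def _read_csv(path: Path) -> SignalRecording:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise DataError(f"{path}: missing required 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least two samples to infer fs")
    fs = 1.0 / np.median(np.diff(t))
    channels: list[tuple[str, str]] = []
    rows = []
    state = None
    for col in df.columns:
        if col == "time":
            continue
        if col == "state":
            state = df[col].to_numpy(dtype=int)
            continue
        if ":" not in col:
            raise DataError(
                f"{path}: channel column {col!r} is not in '<name>:<role>' form"
            )
        name, role = col.rsplit(":", 1)
        if role not in CHANNEL_ROLES:
            raise DataError(f"{path}: column {col!r} has unknown role {role!r}")
        channels.append((name, role))
        rows.append(df[col].to_numpy(dtype=float))
    if not channels:
        raise DataError(f"{path}: no channel columns found")
    return SignalRecording(
        samples=np.vstack(rows), fs=fs, channels=channels, state_track=state
    )


def write_recording(rec: SignalRecording, path: str | Path) -> None:
    """Write a recording as EDF (``.edf``) or CSV (``.csv``) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    elif path.suffix.lower() == ".csv":
        _write_csv(rec, path)
    else:
        raise ConfigError(f"unsupported recording format {path.suffix!r}")


def read_recording(path: str | Path) -> SignalRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise ConfigError(f"unsupported recording format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Feature datasets and simulation configs
# ---------------------------------------------------------------------------

def write_feature_dataset(ds: LabeledDataset, path: str | Path) -> None:
    """Feature CSV with columns ``label,f1..fD``."""
    cols = {"label": ds.y}
    for j in range(ds.X.shape[1]):
        cols[f"f{j + 1}"] = ds.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_feature_dataset(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise DataError(f"{path}: missing required 'label' column")
    feat_cols = [c for c in df.columns if c != "label"]
    if not feat_cols:
        raise DataError(f"{path}: no feature columns")
    return LabeledDataset(
        X=df[feat_cols].to_numpy(dtype=float), y=df["label"].to_numpy(dtype=int)
    )


_STATE_NAMES = {"awake": 0, "fatigue": 1}


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Flat ``key = value`` file covering every SimulationConfig field."""
    lines = [
        f"duration_s = {config.duration_s}",
        f"fs = {config.fs}",
        f"epoch_len_s = {config.epoch_len_s}",
        f"noise_sd = {config.noise_sd}",
        f"blink_amplitude_uv = {config.blink_amplitude_uv}",
        f"seed = {config.seed}",
    ]
    sched = config.resolved_schedule()
    lines.append(
        "state_schedule = " + ",".join(f"{s}:{d}" for s, d in sched)
    )
    for state, sname in ((0, "awake"), (1, "fatigue")):
        for band, p in config.band_power_map.get(state, {}).items():
            lines.append(f"band_power.{sname}.{band} = {p}")
        lines.append(
            f"blink_rate.{sname} = {config.blink_rate_per_state.get(state, 0.0)}"
        )
        lines.append(
            "closure_duration."
            f"{sname} = {config.closure_duration_per_state.get(state, 0.0)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimulationConfig:
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def popf(key: str, default: float) -> float:
        return float(kv.pop(key)) if key in kv else default

    band_power: dict[int, dict[str, float]] = {0: {}, 1: {}}
    blink_rate: dict[int, float] = {}
    closure: dict[int, float] = {}
    for key in list(kv):
        parts = key.split(".")
        if parts[0] == "band_power" and len(parts) == 3:
            band_power[_STATE_NAMES[parts[1]]][parts[2]] = float(kv.pop(key))
        elif parts[0] == "blink_rate" and len(parts) == 2:
            blink_rate[_STATE_NAMES[parts[1]]] = float(kv.pop(key))
        elif parts[0] == "closure_duration" and len(parts) == 2:
            closure[_STATE_NAMES[parts[1]]] = float(kv.pop(key))

    schedule = None
    if "state_schedule" in kv:
        schedule = []
        for item in kv.pop("state_schedule").split(","):
            s, _, d = item.partition(":")
            schedule.append((int(s), float(d)))

    cfg = dict(
        duration_s=popf("duration_s", 64.0),
        fs=popf("fs", 1000.0),
        epoch_len_s=popf("epoch_len_s", 8.0),
        noise_sd=popf("noise_sd", 1.0),
        blink_amplitude_uv=popf("blink_amplitude_uv", 300.0),
        seed=int(popf("seed", 0)),
        state_schedule=schedule,
    )
    if any(band_power.values()):
        cfg["band_power_map"] = band_power
    if blink_rate:
        cfg["blink_rate_per_state"] = blink_rate
    if closure:
        cfg["closure_duration_per_state"] = closure
    if kv:
        raise ConfigError(f"{path}: unknown config keys {sorted(kv)}")
    return SimulationConfig(**cfg)
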