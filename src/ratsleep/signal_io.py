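"""Recording and hypnogram containers, file I/O, and the acquisition filter contract.

Conventions
-----------
* Zeitgeber time (ZT): seconds since lights-on.  ZT 0–12 h is the inactive
  (lights-on) phase for nocturnal rodents, ZT 12–24 h the active phase.
* Epoch timestamps are epoch-start times; epochs are half-open intervals
  ``[start, start + epoch_len)``.
* CSV is the canonical plain-text format; EDF is supported for
  interoperability with polysomnography tooling (16-bit quantization).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

STATES = ("WAKE", "NREM", "REM")

#: canonical channel roles
EEG_ROSTRAL = "EEG_rostral"
EEG_CAUDAL = "EEG_caudal"
EMG = "EMG"

HALF_DAY_S = 12 * 3600.0
DAY_S = 24 * 3600.0

#: acquisition pass-bands, Hz
EEG_BAND = (1.0, 30.0)
EMG_BAND = (10.0, 40.0)


def phase_of_zt(zt_seconds):
    """Light-cycle phase for a ZT timestamp: ``inactive`` iff ZT mod 24 h < 12 h."""
    frac = np.mod(np.asarray(zt_seconds, dtype=float), DAY_S)
    return np.where(frac < HALF_DAY_S, "inactive", "active")


@dataclass
class Recording:
    """Multichannel signal with sampling rate, channel roles and ZT alignment.

    Parameters
    ----------
    data : dict
        Mapping from channel role (``EEG_rostral``, ``EEG_caudal``, ``EMG``)
        to a 1-D sample array in arbitrary amplitude units.
    fs : float
        Sampling rate in Hz.
    zt_start : float
        Zeitgeber time of the first sample, in seconds since lights-on.
    """

    data: dict[str, np.ndarray]
    fs: float
    zt_start: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.data:
            raise ValueError("recording must contain at least one channel")
        lengths = {role: len(x) for role, x in self.data.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        self.data = {role: np.asarray(x) for role, x in self.data.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def eeg_roles(self) -> tuple[str, ...]:
        return tuple(r for r in self.data if r.upper().startswith("EEG"))

    def channel(self, role: str) -> np.ndarray:
        if role not in self.data:
            raise KeyError(f"no channel with role {role!r}; have {list(self.data)}")
        return self.data[role]


@dataclass
class Hypnogram:
    """Epoch-wise vigilance-state labels on a fixed grid.

    ``epoch_zt`` gives the ZT start time of every epoch.  It defaults to the
    regular grid ``zt_start + i * epoch_len`` but may be set explicitly, which
    lets phase-restricted sub-hypnograms keep correct timing even when their
    epochs are not contiguous.
    """

    labels: np.ndarray
    epoch_len: float
    zt_start: float = 0.0
    epoch_zt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="U4")
        if self.labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance states {sorted(bad)}; allowed: {STATES}")
        if self.epoch_len <= 0:
            raise ValueError("epoch length must be positive")
        if self.epoch_zt is None:
            self.epoch_zt = self.zt_start + np.arange(self.labels.size) * float(self.epoch_len)
        else:
            self.epoch_zt = np.asarray(self.epoch_zt, dtype=float)
            if self.epoch_zt.shape != self.labels.shape:
                raise ValueError("epoch_zt must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    @property
    def phases(self) -> np.ndarray:
        """Per-epoch light-cycle phase (``inactive``/``active``), from epoch start."""
        return phase_of_zt(self.epoch_zt)

    def is_contiguous(self) -> bool:
        if self.n_epochs < 2:
            return True
        return bool(np.allclose(np.diff(self.epoch_zt), self.epoch_len))


# ---------------------------------------------------------------------------
# filtering

def bandpass(recording: Recording, role: str, low: float, high: float,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of one channel.

    Forward–backward filtering (``sosfiltfilt``) doubles the effective order
    and removes phase distortion.  Out-of-band tones are attenuated by well
    over 20 dB one octave outside the corners at the default order.
    """
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"corner frequencies must satisfy 0 < low < high < fs/2; "
            f"got low={low}, high={high}, fs/2={nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.channel(role))
    data = dict(recording.data)
    data[role] = filtered
    return replace(recording, data=data)


def apply_acquisition_filters(recording: Recording) -> Recording:
    """Apply the acquisition contract: EEG 1–30 Hz, EMG 10–40 Hz."""
    out = recording
    for role in recording.roles:
        lo, hi = EMG_BAND if role.upper().startswith("EMG") else EEG_BAND
        out = bandpass(out, role, lo, hi)
    return out


# ---------------------------------------------------------------------------
# recording I/O

def write_recording_csv(recording: Recording, path) -> None:
    """Write a recording as CSV with a time column ``t`` (seconds, ZT)."""
    t = recording.zt_start + np.arange(recording.n_samples) / recording.fs
    # fixed-decimal time stamps stay uniform after parsing even at large ZT
    df = pd.DataFrame({"t": [f"{v:.4f}" for v in t],
                       **{r: recording.data[r] for r in recording.roles}})
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path, channel_map: dict[str, str] | None = None) -> Recording:
    """Read a CSV recording; sampling rate is inferred from ``t`` spacing."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError(f"{path}: expected a time column named 't'")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    data = {}
    for col in df.columns:
        if col == "t":
            continue
        role = (channel_map or {}).get(col, col)
        data[role] = df[col].to_numpy(dtype=float)
    return Recording(data=data, fs=round(fs, 6), zt_start=float(t[0]))


# --- EDF -------------------------------------------------------------------
# A minimal EDF writer (fixed-width ASCII header + little-endian int16 data
# records).  Reading goes through MNE, which ships a full EDF reader; MNE's
# EDF export backend is an optional extra, so writing is done here directly.

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path) -> None:
    """Write a recording to EDF (16-bit).  Amplitudes are stored as microvolts.

    The recording length must be a whole number of 1 s data records.
    """
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records, rem = divmod(recording.n_samples, spr)
    if rem:
        raise ValueError("EDF export requires a whole number of 1 s records")
    roles = list(recording.roles)
    ns = len(roles)

    phys_min, phys_max, digital = {}, {}, {}
    for role in roles:
        x = np.asarray(recording.data[role], dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # headroom so rounding in the 8-char header fields never clips
        span = hi - lo
        lo -= 0.01 * span
        hi += 0.01 * span
        lo, hi = round(lo, 3), round(hi, 3)
        scale = (hi - lo) / (32767 - (-32768))
        dig = np.round((x - lo) / scale - 32768).astype("<i2")
        phys_min[role], phys_max[role], digital[role] = lo, hi, dig

    header = b"".join([
        _edf_ascii(0, 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii("01.01.00", 8),
        _edf_ascii("00.00.00", 8),
        _edf_ascii(256 * (ns + 1), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_records, 8),
        _edf_ascii(1, 8),
        _edf_ascii(ns, 4),
    ])
    header += b"".join(_edf_ascii(role, 16) for role in roles)
    header += b"".join(_edf_ascii("", 80) for _ in roles)
    header += b"".join(_edf_ascii("uV", 8) for _ in roles)
    header += b"".join(_edf_ascii(phys_min[r], 8) for r in roles)
    header += b"".join(_edf_ascii(phys_max[r], 8) for r in roles)
    header += b"".join(_edf_ascii(-32768, 8) for _ in roles)
    header += b"".join(_edf_ascii(32767, 8) for _ in roles)
    header += b"".join(_edf_ascii("", 80) for _ in roles)
    header += b"".join(_edf_ascii(spr, 8) for _ in roles)
    header += b"".join(_edf_ascii("", 32) for _ in roles)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for role in roles:
                fh.write(digital[role][rec * spr:(rec + 1) * spr].tobytes())


def read_recording_edf(path, channel_map: dict[str, str] | None = None,
                       zt_start: float = 0.0) -> Recording:
    """Read an EDF recording via MNE.  Amplitudes are returned in microvolts."""
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = {}
    for name in raw.ch_names:
        role = (channel_map or {}).get(name, name)
        # MNE rescales EDF physical dimensions to SI volts
        data[role] = raw.get_data(picks=[name])[0] * 1e6
    return Recording(data=data, fs=float(raw.info["sfreq"]), zt_start=zt_start)


def read_recording(path, fmt: str | None = None,
                   channel_map: dict[str, str] | None = None) -> Recording:
    """Read a recording from EDF or CSV; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_recording_edf(path, channel_map)
    if fmt == "csv":
        return read_recording_csv(path, channel_map)
    raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")


# ---------------------------------------------------------------------------
# hypnogram I/O: CSV dialect  epoch_index,zt_seconds,state

def write_hypnogram(hyp: Hypnogram, path, epoch_len_comment: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        if epoch_len_comment:
            fh.write(f"# epoch_len={hyp.epoch_len}\n")
        w = csv.writer(fh)
        w.writerow(["epoch_index", "zt_seconds", "state"])
        for i, (zt, s) in enumerate(zip(hyp.epoch_zt, hyp.labels)):
            w.writerow([i, f"{zt:g}", s])


def read_hypnogram(path, epoch_len: float | None = None) -> Hypnogram:
    """Read a hypnogram CSV; raises on unknown state tokens, naming the row."""
    header_epoch_len = None
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "epoch_len=" in line:
                    header_epoch_len = float(line.split("epoch_len=")[1])
                continue
            rows.append(line)
    if not rows:
        raise ValueError(f"{path}: empty hypnogram file")
    reader = csv.DictReader(rows)
    if reader.fieldnames is None or "state" not in reader.fieldnames:
        raise ValueError(f"{path}: expected columns epoch_index,zt_seconds,state")
    zts, labels = [], []
    for lineno, row in enumerate(reader, start=2):
        state = row["state"].strip()
        if state not in STATES:
            raise ValueError(
                f"{path}, row {lineno}: unknown state token {state!r}; "
                f"allowed: {'/'.join(STATES)}")
        labels.append(state)
        zts.append(float(row["zt_seconds"]))
    if not labels:
        raise ValueError(f"{path}: hypnogram has a header but no epochs")
    zts = np.asarray(zts)
    if epoch_len is None:
        if header_epoch_len is not None:
            epoch_len = header_epoch_len
        elif len(zts) > 1:
            epoch_len = float(zts[1] - zts[0])
        else:
            raise ValueError(f"{path}: cannot infer epoch length from a single epoch")
    return Hypnogram(labels=np.asarray(labels), epoch_len=epoch_len,
                     zt_start=float(zts[0]), epoch_zt=zts)
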