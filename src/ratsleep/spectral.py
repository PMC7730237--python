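"""Sleep microarchitecture: per-state pooled Welch spectra and relative power.

EEG epochs of one vigilance state inside an analysis window are pooled and a
Welch power spectral density is computed with NFFT = 256 at fs = 200 Hz,
i.e. a frequency resolution of 200/256 = 0.78125 Hz.  Relative power is the
absolute power per bin divided by the summed absolute power over the
normalisation band 1-30 Hz.  Band powers use half-open intervals on bin
centers (delta [1,4), theta [4,8), alpha [8,14), beta [14,30) Hz) so the
bands partition the normalisation range exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from ratsleep.signal_io import Hypnogram, Recording, phase_of_zt

#: rat EEG band edges in Hz, half-open [lo, hi)
DEFAULT_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
                 "alpha": (8.0, 14.0), "beta": (14.0, 30.0)}


@dataclass
class SpectralConfig:
    fs: float = 200.0
    nfft: int = 256
    norm_band: tuple[float, float] = (1.0, 30.0)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    window: str = "hamming"
    overlap: float = 0.5

    def __post_init__(self):
        if not (0 <= self.norm_band[0] < self.norm_band[1] <= self.fs / 2):
            raise ValueError("normalisation band must lie within [0, fs/2]")

    @property
    def resolution(self) -> float:
        """Frequency bin width fs / NFFT (0.78125 Hz at defaults)."""
        return self.fs / self.nfft


@dataclass
class SpectralResult:
    freqs: np.ndarray
    power: np.ndarray  # absolute PSD, amplitude^2 / Hz
    relative: np.ndarray | None = None
    state: str | None = None
    channel: str | None = None
    phase: str | None = None
    n_epochs: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"freq_hz": self.freqs, "power": self.power})
        if self.relative is not None:
            df["relative"] = self.relative
        for k in ("state", "channel", "phase"):
            v = getattr(self, k)
            if v is not None:
                df[k] = v
        return df


class AbsentREM:
    """Marker: the animal has no epochs of the requested state in the whole
    light/dark phase, so it must be excluded from group statistics for that
    state (as happens with REM-free animals)."""

    def __init__(self, state: str, phase: str):
        self.state = state
        self.phase = phase

    def __repr__(self):
        return f"AbsentREM(state={self.state!r}, phase={self.phase!r})"


def pool_state_epochs(recording: Recording, hyp: Hypnogram, state: str,
                      window: tuple[float, float], role: str):
    """Collect the signal of all epochs of one state within a ZT window.

    Returns an array of shape (n_epochs, samples_per_epoch), or an
    :class:`AbsentREM` marker.  If the state is REM and the window contains
    none, the temporally closest REM episode (maximal run) in the same
    light/dark phase is substituted — short REM bouts are easily missed by a
    fixed 2 h window, so the nearest episode stands in for the window's REM.
    Only epochs covered by the recording extent are eligible.
    """
    spe = hyp.epoch_len * recording.fs
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("hypnogram epoch length is not a whole number of samples")
    spe = int(round(spe))
    x = recording.channel(role)
    rec_t0 = recording.zt_start
    rec_t1 = rec_t0 + recording.n_samples / recording.fs

    covered = ((hyp.epoch_zt >= rec_t0 - 1e-9)
               & (hyp.epoch_zt + hyp.epoch_len <= rec_t1 + 1e-9))
    of_state = hyp.labels == state

    t0, t1 = window
    in_window = (hyp.epoch_zt >= t0 - 1e-9) & (hyp.epoch_zt + hyp.epoch_len <= t1 + 1e-9)
    idx = np.flatnonzero(of_state & in_window & covered)

    if idx.size == 0 and state == "REM":
        idx = _closest_episode(hyp, state, window, covered)
    if idx.size == 0:
        return AbsentREM(state=state, phase=str(phase_of_zt(t0)))

    starts = np.round((hyp.epoch_zt[idx] - rec_t0) * recording.fs).astype(int)
    return np.stack([x[s:s + spe] for s in starts])


def _closest_episode(hyp: Hypnogram, state: str, window, covered) -> np.ndarray:
    """Epoch indices of the run of ``state`` closest to the window, same phase."""
    phase = str(phase_of_zt(window[0]))
    eligible = (hyp.labels == state) & covered & (hyp.phases == phase)
    if not eligible.any():
        return np.array([], dtype=int)
    # runs of consecutive eligible epochs of the state
    idx = np.flatnonzero(eligible)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    center = 0.5 * (window[0] + window[1])
    dist = [min(abs(hyp.epoch_zt[r[0]] - center),
                abs(hyp.epoch_zt[r[-1]] + hyp.epoch_len - center)) for r in runs]
    return runs[int(np.argmin(dist))]


def welch_psd(epochs: np.ndarray, config: SpectralConfig | None = None,
              **labels) -> SpectralResult:
    """Welch PSD pooled over epochs (Hamming window, 50% overlap segments).

    Each epoch is segmented independently, so no segment spans the join
    between two pooled (non-contiguous) epochs; the per-segment periodograms
    are averaged across all epochs.
    """
    config = config or SpectralConfig()
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.size == 0:
        raise ValueError("empty epoch pool (no signal to analyse)")
    if epochs.shape[1] < config.nfft:
        raise ValueError(
            f"epochs of {epochs.shape[1]} samples are shorter than NFFT={config.nfft}")
    noverlap = int(config.nfft * config.overlap)
    freqs, psd = sps.welch(epochs, fs=config.fs, window=config.window,
                           nperseg=config.nfft, noverlap=noverlap,
                           nfft=config.nfft, detrend=False, axis=-1)
    return SpectralResult(freqs=freqs, power=psd.mean(axis=0),
                          n_epochs=epochs.shape[0], **labels)


def relative_power(result: SpectralResult,
                   config: SpectralConfig | None = None) -> SpectralResult:
    """Normalise to relative power over the 1-30 Hz band.

    Bins whose center lies in the normalisation band are divided by their
    sum; bins outside the band are dropped from the output.
    """
    config = config or SpectralConfig()
    lo, hi = config.norm_band
    sel = (result.freqs >= lo) & (result.freqs <= hi)
    total = result.power[sel].sum()
    if total <= 0:
        raise ValueError("zero total power in the normalisation band")
    return replace(result, freqs=result.freqs[sel], power=result.power[sel],
                   relative=result.power[sel] / total)


def band_power(result: SpectralResult,
               bands: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """Sum of relative power over bins whose center lies in [lo, hi) per band."""
    if result.relative is None:
        raise ValueError("band_power requires a relative-power result")
    bands = bands or DEFAULT_BANDS
    fmin, fmax = result.freqs.min(), result.freqs.max()
    out = {}
    for name, (lo, hi) in bands.items():
        if lo > hi:
            raise ValueError(f"band {name}: lo > hi")
        if hi < fmin or lo > fmax:
            raise ValueError(f"band {name} [{lo}, {hi}) lies outside the grid")
        sel = (result.freqs >= lo) & (result.freqs < hi)
        out[name] = float(result.relative[sel].sum())
    return out


def state_spectrum(recording: Recording, hyp: Hypnogram, state: str,
                   window: tuple[float, float], role: str,
                   config: SpectralConfig | None = None,
                   per_epoch_norm: bool = False):
    """Pooled relative-power spectrum for one (animal, channel, state, window).

    By default the epoch pool is averaged first and normalised once.  With
    ``per_epoch_norm`` each epoch's PSD is normalised to relative power
    before averaging, which downweights high-amplitude epochs; the two
    conventions agree when amplitude is stationary across the pool.
    Returns a :class:`SpectralResult` or an :class:`AbsentREM` marker.
    """
    config = config or SpectralConfig()
    pool = pool_state_epochs(recording, hyp, state, window, role)
    if isinstance(pool, AbsentREM):
        return pool
    labels = dict(state=state, channel=role, phase=str(phase_of_zt(window[0])))
    if not per_epoch_norm:
        return relative_power(welch_psd(pool, config, **labels), config)
    rels = [relative_power(welch_psd(ep[None, :], config), config).relative
            for ep in pool]
    one = relative_power(welch_psd(pool[0][None, :], config), config)
    rel = np.mean(rels, axis=0)
    rel = rel / rel.sum()
    return SpectralResult(freqs=one.freqs, power=rel, relative=rel,
                          n_epochs=len(pool), **labels)
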