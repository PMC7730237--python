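"""Semi-automated vigilance-state scoring of 4 s epochs.

A transparent three-rule threshold classifier on spectral features: an
epoch with nuchal EMG activity above a calibrated threshold is WAKE;
otherwise a theta/delta power ratio above threshold indicates REM, else
NREM.  Thresholds are calibrated per recording from feature percentiles
("semi-automated"), and a sparse manual-override table can be applied after
automatic scoring.  Ground-truth hypnograms from the synthetic cohort
generator allow the scorer's error to be quantified (Cohen's kappa and a
per-state confusion matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ratsleep.signal_io import Hypnogram, Recording, STATES

#: scoring feature bands, Hz (half-open)
SCORING_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
                 "alpha": (8.0, 14.0), "beta": (14.0, 30.0)}


@dataclass
class ScoringThresholds:
    emg_wake_threshold: float
    theta_delta_rem_threshold: float
    delta_nrem_threshold: float

    def __post_init__(self):
        for name in ("emg_wake_threshold", "theta_delta_rem_threshold",
                     "delta_nrem_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {"emg_wake_threshold": self.emg_wake_threshold,
                "theta_delta_rem_threshold": self.theta_delta_rem_threshold,
                "delta_nrem_threshold": self.delta_nrem_threshold}


def epoch_features(recording: Recording, epoch_len: float = 4.0,
                   eeg_role: str | None = None,
                   emg_role: str = "EMG") -> pd.DataFrame:
    """Per-epoch EEG band powers, theta/delta ratio and EMG RMS.

    Band powers come from a periodogram of each complete epoch (any trailing
    partial epoch is dropped); the ratio is NaN where delta power is zero.
    """
    eeg_role = eeg_role or recording.eeg_roles[0]
    spe = int(round(epoch_len * recording.fs))
    n_epochs = recording.n_samples // spe
    if n_epochs == 0:
        raise ValueError(
            f"recording of {recording.duration:g}s is shorter than one "
            f"{epoch_len:g}s epoch")
    freqs = np.fft.rfftfreq(spe, d=1.0 / recording.fs)
    rows = {}
    eeg = recording.channel(eeg_role)[:n_epochs * spe].reshape(n_epochs, spe)
    spec = np.abs(np.fft.rfft(eeg, axis=1)) ** 2
    for band, (lo, hi) in SCORING_BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        rows[band] = spec[:, sel].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rows["delta"] > 0, rows["theta"] / rows["delta"], np.nan)
    emg = recording.channel(emg_role)[:n_epochs * spe].reshape(n_epochs, spe)
    df = pd.DataFrame(rows)
    df["theta_delta"] = ratio
    df["emg_rms"] = np.sqrt(np.mean(emg ** 2, axis=1))
    df["epoch_zt"] = recording.zt_start + np.arange(n_epochs) * epoch_len
    return df


def calibrate(features: pd.DataFrame, emg_percentile: float = 60.0,
              delta_percentile: float = 50.0,
              theta_delta_threshold: float = 2.0) -> ScoringThresholds:
    """Derive thresholds from percentiles of a recording's own features.

    The EMG threshold at the 60th percentile assumes the animal sleeps a
    little over half the time, placing the cut near the top of the sleep
    EMG cluster; the theta/delta REM threshold is a fixed ratio.
    """
    for col in ("emg_rms", "delta"):
        vals = features[col].to_numpy(dtype=float)
        if np.ptp(vals[np.isfinite(vals)]) == 0:
            raise ValueError(
                f"feature {col!r} is constant; cannot calibrate thresholds")
    return ScoringThresholds(
        emg_wake_threshold=float(np.percentile(features["emg_rms"], emg_percentile)),
        theta_delta_rem_threshold=theta_delta_threshold,
        delta_nrem_threshold=float(np.percentile(features["delta"], delta_percentile)),
    )


def smooth_singletons(labels: np.ndarray) -> np.ndarray:
    """Absorb single-epoch islands into the preceding state.

    Only epochs whose two neighbours agree with each other but not with the
    epoch are rewritten, so no state can appear that was absent before
    smoothing, and bouts of two or more epochs are untouched.
    """
    out = labels.copy()
    for i in range(1, len(out) - 1):
        if out[i - 1] == out[i + 1] != out[i]:
            out[i] = out[i - 1]
    return out


def score_epochs(features: pd.DataFrame, thresholds: ScoringThresholds,
                 epoch_len: float = 4.0, smooth: bool = True,
                 overrides: pd.DataFrame | None = None) -> Hypnogram:
    """Score each epoch: high EMG -> WAKE; else high theta/delta -> REM; else NREM.

    The EMG rule fires first regardless of EEG content.  ``overrides`` is a
    sparse table with columns (epoch, state) applied after automatic scoring
    and smoothing (the manual part of "semi-automated").
    """
    emg = features["emg_rms"].to_numpy(dtype=float)
    ratio = features["theta_delta"].to_numpy(dtype=float)
    labels = np.full(len(features), "NREM", dtype="U4")
    rem = np.nan_to_num(ratio, nan=0.0) > thresholds.theta_delta_rem_threshold
    labels[rem] = "REM"
    labels[emg > thresholds.emg_wake_threshold] = "WAKE"
    if smooth:
        labels = smooth_singletons(labels)
    if overrides is not None:
        for _, row in overrides.iterrows():
            state = str(row["state"])
            if state not in STATES:
                raise ValueError(f"override row has unknown state {state!r}")
            labels[int(row["epoch"])] = state
    zt0 = float(features["epoch_zt"].iloc[0]) if "epoch_zt" in features else 0.0
    return Hypnogram(labels=labels, epoch_len=epoch_len, zt_start=zt0)


def score_recording(recording: Recording, epoch_len: float = 4.0,
                    **calibrate_kwargs) -> tuple[Hypnogram, ScoringThresholds]:
    """Calibrate on the recording's own features, then score it."""
    feats = epoch_features(recording, epoch_len=epoch_len)
    thr = calibrate(feats, **calibrate_kwargs)
    return score_epochs(feats, thr, epoch_len=epoch_len), thr


def score_agreement(scored: Hypnogram, truth: Hypnogram) -> tuple[float, pd.DataFrame]:
    """Cohen's kappa and the confusion matrix (rows: truth, columns: scored)."""
    if scored.n_epochs != truth.n_epochs or scored.epoch_len != truth.epoch_len:
        raise ValueError(
            f"epoch grids differ: scored {scored.n_epochs}x{scored.epoch_len}s "
            f"vs truth {truth.n_epochs}x{truth.epoch_len}s")
    from sklearn.metrics import cohen_kappa_score, confusion_matrix

    kappa = float(cohen_kappa_score(truth.labels, scored.labels, labels=list(STATES)))
    cm = confusion_matrix(truth.labels, scored.labels, labels=list(STATES))
    return kappa, pd.DataFrame(cm, index=list(STATES), columns=list(STATES))
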