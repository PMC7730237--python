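"""Sleep macroarchitecture: state proportions, bouts, transitions, phase splits.

A *bout* is a maximal run of consecutive epochs in one vigilance state; its
length is the time the animal resided in that state.  Transitions are
counted on the binary WAKE vs SLEEP (NREM and REM combined) partition, the
standard fragmentation measure.  All quantities can be split by light-cycle
phase (inactive = lights on = ZT 0-12 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ratsleep.signal_io import Hypnogram, STATES, phase_of_zt


def state_proportions(hyp: Hypnogram, bin_s: float = 7200.0) -> pd.DataFrame:
    """Fraction of time per vigilance state in consecutive time bins.

    Defaults to 2 h bins, giving 12 bins across a 24 h recording.  Returns a
    DataFrame with columns ``bin_start_zt``, one column per state, and
    ``phase``.  Fractions in each row are nonnegative and sum to 1.
    """
    if bin_s % hyp.epoch_len:
        raise ValueError("bin width must be a multiple of the epoch length")
    per_bin = int(round(bin_s / hyp.epoch_len))
    n_bins = hyp.n_epochs // per_bin
    if n_bins == 0:
        raise ValueError(
            f"hypnogram ({hyp.duration:g}s) is shorter than one bin ({bin_s:g}s)")
    rows = []
    for b in range(n_bins):
        chunk = hyp.labels[b * per_bin:(b + 1) * per_bin]
        zt = hyp.epoch_zt[b * per_bin]
        row = {"bin_start_zt": zt, "phase": str(phase_of_zt(zt))}
        for s in STATES:
            row[s] = np.mean(chunk == s)
        rows.append(row)
    return pd.DataFrame(rows)


def extract_bouts(hyp: Hypnogram, drop_boundary: bool = False) -> pd.DataFrame:
    """Run-length encode a hypnogram into a bout table.

    Columns: ``state``, ``start_zt`` (s), ``duration`` (s), ``phase``.  A
    bout spanning a phase boundary is assigned to the phase of its first
    epoch.  ``drop_boundary`` removes the first and last bout, which are
    truncated by the recording limits.
    """
    labels = hyp.labels
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    lengths = np.diff(np.r_[starts, labels.size])
    df = pd.DataFrame({
        "state": labels[starts],
        "start_zt": hyp.epoch_zt[starts],
        "duration": lengths * hyp.epoch_len,
    })
    df["phase"] = phase_of_zt(df["start_zt"].to_numpy())
    if drop_boundary and len(df) > 2:
        df = df.iloc[1:-1].reset_index(drop=True)
    return df


@dataclass
class BoutECDF:
    """Empirical cumulative distribution of bout lengths.

    Right-continuous step function from 0 to 1; ``quantile`` uses linear
    interpolation between order statistics (the numpy default), so the
    "duration below which 80% of bouts fall" corridor is read off directly.
    """

    durations: np.ndarray  # sorted

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        res = np.searchsorted(self.durations, x, side="right") / self.durations.size
        return float(res) if res.ndim == 0 else res

    def quantile(self, q: float) -> float:
        return float(np.percentile(self.durations, 100.0 * q))

    @property
    def n(self) -> int:
        return self.durations.size


class EmptyBoutDistribution(Exception):
    """No bouts of the requested state/phase exist (e.g. a REM-free animal)."""


def bout_cumprob(bouts: pd.DataFrame, state: str,
                 phase: str | None = None) -> BoutECDF:
    """ECDF of bout lengths for one state (optionally one phase)."""
    sel = bouts[bouts["state"] == state]
    if phase is not None:
        sel = sel[sel["phase"] == phase]
    if sel.empty:
        raise EmptyBoutDistribution(
            f"no {state} bouts" + (f" in {phase} phase" if phase else ""))
    return BoutECDF(np.sort(sel["duration"].to_numpy(dtype=float)))


@dataclass
class TransitionCount:
    """WAKE<->SLEEP transition counts on one epoch basis."""

    n_wake_to_sleep: int
    n_sleep_to_wake: int
    epoch_len: float
    phase: str | None = None

    @property
    def total(self) -> int:
        return self.n_wake_to_sleep + self.n_sleep_to_wake


def count_transitions(hyp: Hypnogram, phase: str | None = None) -> TransitionCount:
    """Count transitions across the binary WAKE vs {NREM u REM} partition.

    NREM<->REM changes are not transitions.  When ``phase`` is given, only
    changes between temporally adjacent epochs that both lie in that phase
    are counted (sub-hypnograms from :func:`split_phase` are handled
    correctly: gaps between non-contiguous epochs never count).
    """
    awake = hyp.labels == "WAKE"
    adjacent = np.isclose(np.diff(hyp.epoch_zt), hyp.epoch_len)
    if phase is not None:
        in_phase = hyp.phases == phase
        adjacent &= in_phase[:-1] & in_phase[1:]
    w2s = int(np.sum(awake[:-1] & ~awake[1:] & adjacent))
    s2w = int(np.sum(~awake[:-1] & awake[1:] & adjacent))
    return TransitionCount(n_wake_to_sleep=w2s, n_sleep_to_wake=s2w,
                           epoch_len=hyp.epoch_len, phase=phase)


def split_phase(hyp: Hypnogram) -> tuple[Hypnogram, Hypnogram]:
    """Partition a hypnogram into its inactive and active epochs.

    The two sub-hypnograms carry explicit epoch timestamps (they are not
    necessarily contiguous, e.g. for a recording that wraps past ZT 24 h);
    interleaving them by timestamp restores the original exactly.
    """
    phases = hyp.phases
    parts = []
    for ph in ("inactive", "active"):
        sel = phases == ph
        if not sel.any():
            parts.append(None)
            continue
        parts.append(Hypnogram(labels=hyp.labels[sel], epoch_len=hyp.epoch_len,
                               zt_start=float(hyp.epoch_zt[sel][0]),
                               epoch_zt=hyp.epoch_zt[sel]))
    return tuple(parts)  # type: ignore[return-value]


def macro_summary(hyp: Hypnogram, bin_s: float = 7200.0) -> dict:
    """Convenience bundle of the macroarchitecture outputs for one animal."""
    bouts = extract_bouts(hyp)
    out = {
        "proportions": state_proportions(hyp, bin_s),
        "bouts": bouts,
        "transitions": {ph: count_transitions(hyp, phase=ph)
                        for ph in ("inactive", "active")},
    }
    return out
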