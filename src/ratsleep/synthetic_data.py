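"""Synthetic cohorts of rodent sleep EEG/EMG recordings with ground truth.

The generator emulates 24 h two-channel EEG + nuchal EMG recordings at
200 Hz under a 12:12 light/dark cycle.  Vigilance follows a phase-dependent
semi-Markov chain over WAKE/NREM/REM: per-state bout durations are drawn
from lognormal distributions (heavy right tail, matching the gradual
approach of empirical bout-length cumulative probability curves to 1) and
the next state from a 3x3 zero-diagonal transition matrix.  Within each
state the EEG is synthesised by spectrally shaping Gaussian noise so that
its expected relative band powers match a per-state recipe: band-limited
oscillator components (delta-dominant NREM, theta-dominant REM/WAKE) plus a
1/f broadband remainder on 1-30 Hz.  EMG is 10-40 Hz noise whose amplitude
is high in WAKE, low in NREM and minimal in REM.

Group differences ("effect profiles") are expressed as multipliers on mean
bout duration, a global transition-rate multiplier, shifted relative-power
recipes, a broadband-noise shift that raises or lowers sign-pattern entropy,
and a per-animal probability of lacking REM in an analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ratsleep.signal_io import (
    DAY_S,
    EEG_CAUDAL,
    EEG_ROSTRAL,
    EMG,
    Hypnogram,
    Recording,
    STATES,
    phase_of_zt,
    write_hypnogram,
    write_recording_csv,
    write_recording_edf,
)

BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
         "alpha": (8.0, 14.0), "beta": (14.0, 30.0)}
EEG_LIMITS = (1.0, 30.0)
EMG_LIMITS = (10.0, 40.0)

#: per-state EMG root-mean-square amplitude (arbitrary units)
EMG_AMPLITUDE = {"WAKE": 1.0, "NREM": 0.25, "REM": 0.08}
#: per-state overall EEG amplitude (arbitrary units; relative power is what matters)
EEG_AMPLITUDE = {"WAKE": 1.0, "NREM": 1.5, "REM": 0.8}

#: default per-state relative-power recipes (fractions of 1-30 Hz power;
#: the remainder is 1/f broadband noise)
DEFAULT_RELPOWER = {
    "WAKE": {"delta": 0.20, "theta": 0.30, "alpha": 0.15, "beta": 0.15},
    "NREM": {"delta": 0.60, "theta": 0.15, "alpha": 0.08, "beta": 0.05},
    "REM": {"delta": 0.10, "theta": 0.50, "alpha": 0.15, "beta": 0.10},
}


@dataclass
class SemiMarkovParams:
    """Base semi-Markov parameters for one light-cycle phase.

    ``transition[s]`` maps each state to the distribution over next states;
    rows must have a zero diagonal and sum to 1.
    """

    mean_bout: dict[str, float]
    transition: dict[str, dict[str, float]]
    sigma: float = 0.8  # lognormal shape (log-space SD) shared across states

    def validate(self) -> None:
        for s in STATES:
            if self.mean_bout.get(s, 0) <= 0:
                raise ValueError(f"mean bout duration for {s} must be positive")
            row = self.transition.get(s, {})
            if row.get(s, 0.0) != 0.0:
                raise ValueError(f"transition matrix diagonal must be zero ({s})")
            total = sum(row.get(t, 0.0) for t in STATES if t != s)
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"transition row for {s} must sum to 1 excluding the "
                    f"diagonal; sums to {total}")


def default_phase_params() -> dict[str, SemiMarkovParams]:
    """Baseline dynamics for a healthy aged rat.

    Inactive (lights-on) phase: sleep-dominated, short WAKE bouts; active
    phase: long WAKE bouts, shorter sleep bouts.  REM is entered almost
    exclusively from NREM.  Values are free modelling choices; the lognormal
    means are in seconds.
    """
    inactive = SemiMarkovParams(
        mean_bout={"WAKE": 90.0, "NREM": 170.0, "REM": 80.0},
        transition={
            "WAKE": {"NREM": 0.95, "REM": 0.05},
            "NREM": {"WAKE": 0.55, "REM": 0.45},
            "REM": {"WAKE": 0.70, "NREM": 0.30},
        },
    )
    active = SemiMarkovParams(
        mean_bout={"WAKE": 340.0, "NREM": 100.0, "REM": 60.0},
        transition={
            "WAKE": {"NREM": 0.95, "REM": 0.05},
            "NREM": {"WAKE": 0.70, "REM": 0.30},
            "REM": {"WAKE": 0.85, "NREM": 0.15},
        },
    )
    return {"inactive": inactive, "active": active}


@dataclass
class GroupEffectProfile:
    """Tunable group-level effects layered on the base dynamics."""

    bout_scale: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STATES})
    transition_rate_scale: float = 1.0
    relpower_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(DEFAULT_RELPOWER[s]) for s in STATES})
    eod_shift: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STATES})
    rem_deficit_prob: float = 0.0
    #: SD of the per-animal multiplicative jitter on mean bout durations
    bout_jitter: float = 0.15
    #: SD of per-animal additive jitter on each band's relative-power target
    relpower_jitter: float = 0.02

    def __post_init__(self):
        for s, v in self.bout_scale.items():
            if v <= 0:
                raise ValueError(f"bout_scale[{s}] must be positive")
        if self.transition_rate_scale <= 0:
            raise ValueError("transition_rate_scale must be positive")
        for s, prof in self.relpower_profile.items():
            if any(p < 0 for p in prof.values()):
                raise ValueError(f"relative-power targets for {s} must be nonnegative")
            if sum(prof.values()) > 1 + 1e-9:
                raise ValueError(
                    f"relative-power targets for {s} sum to more than 1 "
                    "(remainder is broadband noise)")
        if not 0 <= self.rem_deficit_prob <= 1:
            raise ValueError("rem_deficit_prob must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-level simulation settings."""

    duration: float = DAY_S
    fs: float = 200.0
    seed: int = 0
    macro_epoch: float = 10.0
    micro_epoch: float = 4.0
    zt_start: float = 0.0
    #: restrict EEG synthesis to these ZT windows (seconds); None = full record
    eeg_windows: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.duration <= 0 or self.duration % self.macro_epoch:
            raise ValueError("duration must be a positive multiple of the macro epoch")
        if self.fs <= 2 * EMG_LIMITS[1]:
            raise ValueError(
                f"fs must exceed twice the highest synthesized frequency "
                f"({EMG_LIMITS[1]} Hz)")


@dataclass
class SimulatedAnimal:
    animal_id: str
    group: str
    truth_macro: Hypnogram
    truth_micro: Hypnogram
    recordings: list[Recording]
    bouts: list[tuple[str, float]]  # (state, duration s), micro-epoch granular

    @property
    def recording(self) -> Recording:
        if len(self.recordings) != 1:
            raise ValueError(
                f"animal {self.animal_id} has {len(self.recordings)} recordings; "
                "access .recordings for windowed cohorts")
        return self.recordings[0]


# ---------------------------------------------------------------------------
# hypnogram simulation

def _draw_bouts(config: SimulationConfig, profile: GroupEffectProfile,
                params: dict[str, SemiMarkovParams], rng: np.random.Generator,
                bout_scale_jitter: dict[str, float] | None = None,
                allow_rem: bool = True) -> list[tuple[str, float]]:
    """Draw a bout sequence covering ``config.duration`` seconds.

    Durations are rounded to the micro-epoch grid (minimum one micro epoch)
    so both the 4 s and the 10 s label grids derive from one sequence.
    """
    for p in params.values():
        p.validate()
    jit = bout_scale_jitter or {s: 1.0 for s in STATES}
    order = list(STATES)
    t = 0.0
    # start from the time-weighted stationary law of the starting phase
    phase0 = str(phase_of_zt(config.zt_start))
    w = stationary_proportions(params[phase0], profile)
    state = rng.choice(order, p=[w[s] for s in order])
    bouts: list[tuple[str, float]] = []
    while t < config.duration:
        phase = str(phase_of_zt((config.zt_start + t) % DAY_S))
        p = params[phase]
        mean = (p.mean_bout[state] * profile.bout_scale.get(state, 1.0)
                * jit[state] / profile.transition_rate_scale)
        mu = np.log(mean) - p.sigma ** 2 / 2.0
        dur = float(rng.lognormal(mu, p.sigma))
        dur = max(config.micro_epoch,
                  round(dur / config.micro_epoch) * config.micro_epoch)
        dur = min(dur, config.duration - t)
        bouts.append((state, dur))
        t += dur
        row = dict(p.transition[state])
        if not allow_rem:
            row.pop("REM", None)
        nxt = [s for s in order if s != state and row.get(s, 0) > 0]
        if not nxt:
            # degenerate chain: remain in an absorbing-like cycle
            nxt = [s for s in order if s != state]
            probs = None
        else:
            probs = np.array([row[s] for s in nxt])
            probs = probs / probs.sum()
        state = rng.choice(nxt, p=probs)
    # rounding may leave a sub-epoch remainder on the final bout
    total = sum(d for _, d in bouts)
    if total > config.duration:
        s, d = bouts[-1]
        bouts[-1] = (s, d - (total - config.duration))
    return [(s, d) for s, d in bouts if d > 0]


def _labels_from_bouts(bouts, epoch_len: float, duration: float) -> np.ndarray:
    """Label each epoch by the state at its midpoint."""
    edges = np.cumsum([0.0] + [d for _, d in bouts])
    states = np.array([s for s, _ in bouts], dtype="U4")
    n = int(round(duration / epoch_len))
    mids = (np.arange(n) + 0.5) * epoch_len
    idx = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0, len(states) - 1)
    return states[idx]


def simulate_hypnogram(config: SimulationConfig, profile: GroupEffectProfile,
                       params: dict[str, SemiMarkovParams] | None = None,
                       rng: np.random.Generator | None = None,
                       epoch_len: float | None = None) -> Hypnogram:
    """Simulate a hypnogram at ``epoch_len`` (default: the macro epoch)."""
    params = params or default_phase_params()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bouts = _draw_bouts(config, profile, params, rng)
    epoch_len = epoch_len or config.macro_epoch
    labels = _labels_from_bouts(bouts, epoch_len, config.duration)
    return Hypnogram(labels=labels, epoch_len=epoch_len, zt_start=config.zt_start)


def stationary_proportions(params: SemiMarkovParams,
                           profile: GroupEffectProfile | None = None) -> dict[str, float]:
    """Long-run time proportions of the semi-Markov chain (renewal theory).

    The embedded-chain stationary vector pi solves pi P = pi; the fraction of
    time in state s is pi_s * E[bout_s] normalised across states.
    """
    params.validate()
    order = list(STATES)
    P = np.array([[params.transition[a].get(b, 0.0) for b in order] for a in order])
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi = pi / pi.sum()
    scale = profile.bout_scale if profile else {s: 1.0 for s in order}
    w = pi * np.array([params.mean_bout[s] * scale.get(s, 1.0) for s in order])
    w = w / w.sum()
    return dict(zip(order, w))


# ---------------------------------------------------------------------------
# signal synthesis

def _state_psd_mask(freqs: np.ndarray, relpower: dict[str, float],
                    eod_shift: float) -> np.ndarray:
    """sqrt-PSD shaping mask on the rFFT grid for one vigilance state.

    Band components are spectrally flat within their band; the remainder of
    the 1-30 Hz power budget is 1/f broadband noise.  ``eod_shift`` moves
    power budget from the band components into the broadband remainder
    (positive shift => whiter signal => more uniform sign patterns => higher
    entropy of difference), saturating so fractions stay valid.
    """
    p, phi = _effective_recipe(relpower)
    lo, hi = EEG_LIMITS
    in_eeg = (freqs >= lo) & (freqs <= hi)
    invf = np.zeros_like(freqs)
    invf[in_eeg] = 1.0 / np.maximum(freqs[in_eeg], lo)
    psd = phi * invf / np.log(hi / lo)  # unit-power 1/f floor over 1-30 Hz
    for b, (blo, bhi) in BANDS.items():
        sel = (freqs >= blo) & (freqs < bhi)
        if sel.any():
            psd[sel] += p[b] / (bhi - blo)
    # entropy shift: mix toward in-band white noise (uniform sign patterns,
    # higher EoD) or toward a slow delta-concentrated component (lower EoD)
    s = float(np.clip(eod_shift, -1.0, 1.0))
    if s > 0:
        white = in_eeg.astype(float) / (hi - lo)
        psd = (1 - s) * psd + s * white
    elif s < 0:
        slow = ((freqs >= lo) & (freqs < 3.0)).astype(float) / (3.0 - lo)
        psd = (1 + s) * psd + (-s) * slow
    psd[~in_eeg] = 0.0
    return np.sqrt(psd)


def _effective_recipe(relpower: dict[str, float]):
    """Split the unit power budget into flat band components and a 1/f floor.

    The floor fraction is the profile's remainder 1 - sum(targets); band
    components are rescaled to fill what is left.
    """
    p = {b: relpower.get(b, 0.0) for b in BANDS}
    rem = max(0.0, 1.0 - sum(p.values()))
    phi = float(np.clip(rem, 0.02, 0.95))
    osc_total = sum(p.values())
    if osc_total > 0:
        factor = (1.0 - phi) / osc_total
        p = {b: v * factor for b, v in p.items()}
    return p, phi


def expected_band_fractions(relpower: dict[str, float],
                            eod_shift: float = 0.0) -> dict[str, float]:
    """Realized relative band powers implied by a recipe.

    The four analysis bands tile the 1-30 Hz normalisation range, so the 1/f
    floor's power lands inside them: the realized fraction of band b is its
    flat component plus the floor's share ``phi * ln(hi/lo) / ln(30)``,
    further mixed with the entropy-shift component when one is set.  These
    are the reference values for generator/analysis round-trip checks.
    """
    p, phi = _effective_recipe(relpower)
    lo0, hi0 = EEG_LIMITS
    area = np.log(hi0 / lo0)
    base = {b: p[b] + phi * np.log(hi / lo) / area
            for b, (lo, hi) in BANDS.items()}
    s = float(np.clip(eod_shift, -1.0, 1.0))
    if s > 0:
        width = hi0 - lo0
        return {b: (1 - s) * base[b] + s * (hi - lo) / width
                for b, (lo, hi) in BANDS.items()}
    if s < 0:
        slow = {b: min(max(3.0 - lo, 0.0), hi - lo) / (3.0 - lo0)
                for b, (lo, hi) in BANDS.items()}
        return {b: (1 + s) * base[b] + (-s) * slow[b] for b in BANDS}
    return base


def _shaped_noise(n: int, fs: float, mask_fn, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    x = np.fft.irfft(spec * mask_fn(freqs), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_eeg(hypnogram_or_bouts, profile: GroupEffectProfile,
                 config: SimulationConfig,
                 window: tuple[float, float] | None = None,
                 rng: np.random.Generator | None = None) -> Recording:
    """Synthesize a three-channel recording consistent with a state sequence.

    Accepts either a micro-resolution :class:`Hypnogram` or a bout list
    ``[(state, duration s), ...]``.  If ``window`` is given, only that ZT
    interval is synthesized and the returned recording starts there.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if isinstance(hypnogram_or_bouts, Hypnogram):
        hyp = hypnogram_or_bouts
        spe = config.fs * hyp.epoch_len
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError(
                f"hypnogram epoch length {hyp.epoch_len}s is not a whole "
                f"number of samples at fs={config.fs} Hz")
        bouts, start = [], hyp.zt_start
        for s, d in zip(*_runs(hyp.labels)):
            bouts.append((s, d * hyp.epoch_len))
    else:
        bouts = list(hypnogram_or_bouts)
        start = config.zt_start
    t0, t1 = window if window is not None else (start, start + sum(d for _, d in bouts))
    fs = config.fs
    n_total = int(round((t1 - t0) * fs))
    channels = {EEG_ROSTRAL: np.empty(n_total, dtype=np.float32),
                EEG_CAUDAL: np.empty(n_total, dtype=np.float32),
                EMG: np.empty(n_total, dtype=np.float32)}
    emg_lo, emg_hi = EMG_LIMITS
    t = start
    for state, dur in bouts:
        seg0, seg1 = max(t, t0), min(t + dur, t1)
        t += dur
        if seg1 <= seg0:
            continue
        i0 = int(round((seg0 - t0) * fs))
        i1 = int(round((seg1 - t0) * fs))
        n = i1 - i0
        if n <= 0:
            continue
        relp = profile.relpower_profile[state]
        shift = profile.eod_shift.get(state, 0.0)
        for role in (EEG_ROSTRAL, EEG_CAUDAL):
            x = _shaped_noise(n, fs, lambda f: _state_psd_mask(f, relp, shift), rng)
            channels[role][i0:i1] = EEG_AMPLITUDE[state] * x

        def emg_mask(f, lo=emg_lo, hi=emg_hi):
            m = np.zeros_like(f)
            m[(f >= lo) & (f <= hi)] = 1.0
            return m

        channels[EMG][i0:i1] = EMG_AMPLITUDE[state] * _shaped_noise(n, fs, emg_mask, rng)
    return Recording(data=channels, fs=fs, zt_start=t0)


def _runs(labels: np.ndarray):
    """Run-length encode a label array -> (states, run lengths)."""
    n = len(labels)
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    lengths = np.diff(np.r_[starts, n])
    return labels[starts], lengths


# ---------------------------------------------------------------------------
# cohorts

def _jitter_profile(profile: GroupEffectProfile, rng: np.random.Generator):
    """Per-animal biological variability around the group profile."""
    bout_jit = {s: float(rng.lognormal(0.0, profile.bout_jitter)) for s in STATES}
    relp = {}
    for s, prof in profile.relpower_profile.items():
        prof = {b: max(0.005, v + rng.normal(0.0, profile.relpower_jitter))
                for b, v in prof.items()}
        total = sum(prof.values())
        if total > 0.95:
            prof = {b: v * 0.95 / total for b, v in prof.items()}
        relp[s] = prof
    return bout_jit, replace(profile, relpower_profile=relp)


def simulate_animal(config: SimulationConfig, profile: GroupEffectProfile,
                    group: str, animal_id: str,
                    seed_seq: np.random.SeedSequence,
                    params: dict[str, SemiMarkovParams] | None = None) -> SimulatedAnimal:
    params = params or default_phase_params()
    rng = np.random.default_rng(seed_seq)
    bout_jit, animal_profile = _jitter_profile(profile, rng)
    allow_rem = not (profile.rem_deficit_prob > 0
                     and rng.random() < profile.rem_deficit_prob)
    bouts = _draw_bouts(config, profile, params, rng,
                        bout_scale_jitter=bout_jit, allow_rem=allow_rem)
    micro = Hypnogram(labels=_labels_from_bouts(bouts, config.micro_epoch, config.duration),
                      epoch_len=config.micro_epoch, zt_start=config.zt_start)
    macro = Hypnogram(labels=_labels_from_bouts(bouts, config.macro_epoch, config.duration),
                      epoch_len=config.macro_epoch, zt_start=config.zt_start)
    if config.eeg_windows is None:
        recs = [simulate_eeg(bouts, animal_profile, config, rng=rng)]
    else:
        recs = [simulate_eeg(bouts, animal_profile, config, window=w, rng=rng)
                for w in config.eeg_windows]
    return SimulatedAnimal(animal_id=animal_id, group=group, truth_macro=macro,
                           truth_micro=micro, recordings=recs, bouts=bouts)


def simulate_cohort(config: SimulationConfig,
                    profile_ac: GroupEffectProfile,
                    profile_ad: GroupEffectProfile,
                    n_ac: int = 7, n_ad: int = 8,
                    params: dict[str, SemiMarkovParams] | None = None,
                    out_dir=None, write_edf: bool = False) -> list[SimulatedAnimal]:
    """Simulate a two-group cohort (default 7 control + 8 disease animals).

    Per-animal seeds are spawned from the master seed, so each animal is
    reproducible independently of cohort size ordering.  If ``out_dir`` is
    given, recordings (CSV, optionally EDF) and hypnograms are written there
    together with a ``manifest.csv``.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(n_ac + n_ad)
    animals = []
    specs = [("AC", profile_ac)] * n_ac + [("AD", profile_ad)] * n_ad
    for i, ((group, profile), seq) in enumerate(zip(specs, seqs)):
        aid = f"{group}{i + 1:02d}" if group == "AC" else f"{group}{i + 1 - n_ac:02d}"
        animals.append(simulate_animal(config, profile, group, aid, seq, params))
    if out_dir is not None:
        _write_cohort(animals, Path(out_dir), write_edf)
    return animals


def control_profile() -> GroupEffectProfile:
    """Baseline aged-control effect profile (no group effect)."""
    return GroupEffectProfile()


def ad_like_profile() -> GroupEffectProfile:
    """A disease-like profile: fragmented sleep and a whiter, faster EEG.

    Shorter NREM/REM bouts and more frequent transitions (sleep
    fragmentation), relative power shifted from delta toward theta and the
    higher frequencies, sign-pattern entropy pushed down in WAKE and up in
    NREM (shrinking the WAKE/NREM dynamic range), and a per-animal chance of
    lacking REM in an analysis window.
    """
    return GroupEffectProfile(
        bout_scale={"WAKE": 1.0, "NREM": 0.5, "REM": 0.7},
        transition_rate_scale=1.5,
        relpower_profile={
            "WAKE": {"delta": 0.12, "theta": 0.38, "alpha": 0.17, "beta": 0.18},
            "NREM": {"delta": 0.45, "theta": 0.24, "alpha": 0.11, "beta": 0.08},
            "REM": {"delta": 0.08, "theta": 0.52, "alpha": 0.17, "beta": 0.12},
        },
        eod_shift={"WAKE": -0.10, "NREM": 0.10, "REM": 0.08},
        rem_deficit_prob=0.2,
    )


def _write_cohort(animals: list[SimulatedAnimal], out_dir: Path, write_edf: bool) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in animals:
        hyp10 = out_dir / f"{a.animal_id}_hyp10.csv"
        hyp4 = out_dir / f"{a.animal_id}_hyp4.csv"
        write_hypnogram(a.truth_macro, hyp10)
        write_hypnogram(a.truth_micro, hyp4)
        rec_paths = []
        for j, rec in enumerate(a.recordings):
            p = out_dir / f"{a.animal_id}_rec{j}.csv"
            write_recording_csv(rec, p)
            rec_paths.append(p.name)
            if write_edf:
                write_recording_edf(rec, p.with_suffix(".edf"))
        rows.append({"animal_id": a.animal_id, "group": a.group,
                     "hypnogram_10s": hyp10.name, "hypnogram_4s": hyp4.name,
                     "recordings": ";".join(rec_paths)})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
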