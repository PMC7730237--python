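"""End-to-end study orchestration on a cohort (synthetic or user-supplied).

``run_macro`` reproduces the macroarchitecture analysis: 2 h-bin state
proportions with two-way ANOVA, per-state per-phase bout-length ECDFs with
Anderson-Darling group comparisons, and WAKE/SLEEP transition counts with
AUC effect sizes on both epoch bases (12 h at 10 s; analysis windows at
4 s).  ``run_micro`` reproduces the microarchitecture analysis: group
relative-power curves (median +/- median absolute deviation), per-bin AUC
masks with the two-neighbour rule, band-power AUC tables, and
entropy-of-difference comparisons between groups and between WAKE and NREM
within each group.  ``run_all`` writes everything as CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ratsleep import effect_stats, hypnogram_metrics as hm
from ratsleep.entropy import EoDParams, eod_by_state
from ratsleep.signal_io import Hypnogram, Recording, STATES, phase_of_zt, read_hypnogram, read_recording
from ratsleep.spectral import AbsentREM, SpectralConfig, state_spectrum

log = logging.getLogger("ratsleep")

#: default quantitative-EEG analysis windows: ZT 7-9 h (inactive) and
#: ZT 19-21 h (active), i.e. 2-4 pm and 2-4 am under lights-on at 7 am
DEFAULT_WINDOWS = ((7 * 3600.0, 9 * 3600.0), (19 * 3600.0, 21 * 3600.0))


@dataclass
class CohortAnimal:
    """One animal's data as the pipeline consumes it."""

    animal_id: str
    group: str  # "AC" or "AD"
    hyp_macro: Hypnogram
    hyp_micro: Hypnogram | None = None
    recordings: list[Recording] = field(default_factory=list)

    def recording_covering(self, window) -> Recording | None:
        t0, t1 = window
        for rec in self.recordings:
            if rec.zt_start <= t0 + 1e-9 and rec.zt_start + rec.duration >= t1 - 1e-9:
                return rec
        return None


@dataclass
class StudyConfig:
    windows: tuple = DEFAULT_WINDOWS
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    eod_taus: tuple[int, ...] = (1, 6)
    eod_m: int = 5
    n_boot: int = 10000
    seed: int = 0
    alpha: float = 0.05
    bin_s: float = 7200.0
    channels: tuple[str, ...] = ("EEG_rostral", "EEG_caudal")


def from_simulated(animals) -> list[CohortAnimal]:
    """Adapt :class:`~ratsleep.synthetic_data.SimulatedAnimal` objects."""
    return [CohortAnimal(animal_id=a.animal_id, group=a.group,
                         hyp_macro=a.truth_macro, hyp_micro=a.truth_micro,
                         recordings=list(a.recordings)) for a in animals]


def load_cohort(manifest_path) -> list[CohortAnimal]:
    """Load a cohort from a ``manifest.csv`` written by the simulator or by hand.

    Columns: ``animal_id``, ``group``, ``hypnogram_10s``, optional
    ``hypnogram_4s`` and semicolon-separated ``recordings``; paths are
    relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cohort = []
    for _, row in df.iterrows():
        if row["group"] not in ("AC", "AD"):
            raise ValueError(f"animal {row['animal_id']}: group must be AC or AD")
        hyp_macro = read_hypnogram(base / row["hypnogram_10s"])
        hyp_micro = (read_hypnogram(base / row["hypnogram_4s"])
                     if "hypnogram_4s" in row and pd.notna(row["hypnogram_4s"]) else None)
        recs = []
        if "recordings" in row and pd.notna(row["recordings"]) and row["recordings"]:
            recs = [read_recording(base / p) for p in str(row["recordings"]).split(";")]
        cohort.append(CohortAnimal(animal_id=row["animal_id"], group=row["group"],
                                   hyp_macro=hyp_macro, hyp_micro=hyp_micro,
                                   recordings=recs))
    return cohort


def _by_group(cohort):
    return ([a for a in cohort if a.group == "AC"],
            [a for a in cohort if a.group == "AD"])


# ---------------------------------------------------------------------------
# macroarchitecture

def run_macro(cohort: list[CohortAnimal], config: StudyConfig | None = None) -> dict:
    config = config or StudyConfig()
    ac, ad = _by_group(cohort)
    out: dict = {}

    # state proportions in 2 h bins + two-way ANOVA per state
    prop_rows = []
    for a in cohort:
        props = hm.state_proportions(a.hyp_macro, config.bin_s)
        for _, r in props.iterrows():
            for s in STATES:
                prop_rows.append({"animal_id": a.animal_id, "group": a.group,
                                  "time": r["bin_start_zt"], "state": s,
                                  "value": r[s]})
    props_df = pd.DataFrame(prop_rows)
    out["proportions"] = props_df
    anova = {}
    if ac and ad and props_df["time"].nunique() >= 2:
        for s in STATES:
            sub = props_df[props_df["state"] == s]
            res = effect_stats.proportions_anova(sub, alpha=config.alpha)
            F, p = res.f_p("group")
            anova[s] = {"F_group": F, "p_group": p,
                        "F_time": res.f_p("time")[0], "p_time": res.f_p("time")[1]}
    else:
        log.warning("single-group cohort: ANOVA skipped")
    out["anova"] = anova

    # bouts + Anderson-Darling per state/phase
    bout_rows = []
    for a in cohort:
        b = hm.extract_bouts(a.hyp_macro)
        b.insert(0, "animal_id", a.animal_id)
        b.insert(1, "group", a.group)
        bout_rows.append(b)
    bouts_df = pd.concat(bout_rows, ignore_index=True)
    out["bouts"] = bouts_df
    ad_rows = []
    if ac and ad:
        for s in STATES:
            for ph in ("inactive", "active"):
                xa = bouts_df.query("group == 'AC' and state == @s and phase == @ph")["duration"]
                xb = bouts_df.query("group == 'AD' and state == @s and phase == @ph")["duration"]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                stat, p = effect_stats.anderson_darling_2samp(xa, xb)
                q80 = {g: float(np.percentile(v, 80)) for g, v in
                       (("AC", xa), ("AD", xb))}
                ad_rows.append({"state": s, "phase": ph, "ad_statistic": stat,
                                "p": p, "significant": p < config.alpha,
                                "q80_ac_s": q80["AC"], "q80_ad_s": q80["AD"]})
    out["bout_tests"] = pd.DataFrame(ad_rows)

    # transitions: 12 h phases on the macro grid, analysis windows on the micro grid
    rng = np.random.default_rng(config.seed)
    trans_rows = []
    for a in cohort:
        for ph in ("inactive", "active"):
            tc = hm.count_transitions(a.hyp_macro, phase=ph)
            trans_rows.append({"animal_id": a.animal_id, "group": a.group,
                               "basis": "12h_macro", "phase": ph, "n": tc.total})
        if a.hyp_micro is not None:
            for w in config.windows:
                sel = ((a.hyp_micro.epoch_zt >= w[0])
                       & (a.hyp_micro.epoch_zt + a.hyp_micro.epoch_len <= w[1]))
                if not sel.any():
                    continue
                sub = Hypnogram(labels=a.hyp_micro.labels[sel],
                                epoch_len=a.hyp_micro.epoch_len,
                                zt_start=float(a.hyp_micro.epoch_zt[sel][0]),
                                epoch_zt=a.hyp_micro.epoch_zt[sel])
                tc = hm.count_transitions(sub)
                trans_rows.append({"animal_id": a.animal_id, "group": a.group,
                                   "basis": "window_micro",
                                   "phase": str(phase_of_zt(w[0])), "n": tc.total})
    trans_df = pd.DataFrame(trans_rows)
    out["transitions"] = trans_df
    eff_rows = []
    if ac and ad:
        for (basis, ph), sub in trans_df.groupby(["basis", "phase"]):
            xa = sub[sub["group"] == "AC"]["n"].to_numpy()
            xb = sub[sub["group"] == "AD"]["n"].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            es = effect_stats.bootstrap_auc_ci(xa, xb, n_boot=config.n_boot, seed=rng)
            eff_rows.append({"basis": basis, "phase": ph, **es.as_dict()})
    out["transition_effects"] = pd.DataFrame(eff_rows)
    return out


# ---------------------------------------------------------------------------
# microarchitecture

def _animal_spectra(cohort, config, channel, state, window):
    """Per-animal relative-power rows; animals lacking the state are dropped."""
    rows, freqs, excluded = [], None, []
    for a in cohort:
        rec = a.recording_covering(window)
        if rec is None or a.hyp_micro is None:
            excluded.append(a.animal_id)
            continue
        res = state_spectrum(rec, a.hyp_micro, state, window, channel, config.spectral)
        if isinstance(res, AbsentREM):
            excluded.append(a.animal_id)
            continue
        freqs = res.freqs
        rows.append((a.animal_id, a.group, res.relative))
    return rows, freqs, excluded


def run_micro(cohort: list[CohortAnimal], config: StudyConfig | None = None) -> dict:
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    curves, masks, band_rows, eod_rows = [], {}, [], []
    for window in config.windows:
        phase = str(phase_of_zt(window[0]))
        for channel in config.channels:
            for state in STATES:
                rows, freqs, excluded = _animal_spectra(cohort, config, channel,
                                                        state, window)
                if excluded:
                    log.info("%s/%s/%s: %d animal(s) excluded (no %s): %s",
                             channel, state, phase, len(excluded), state,
                             ",".join(excluded))
                if not rows:
                    continue
                A = np.stack([r[2] for r in rows if r[1] == "AC"]) if any(
                    r[1] == "AC" for r in rows) else None
                B = np.stack([r[2] for r in rows if r[1] == "AD"]) if any(
                    r[1] == "AD" for r in rows) else None
                for grp, mat in (("AC", A), ("AD", B)):
                    if mat is None:
                        continue
                    med = np.median(mat, axis=0)
                    mad = np.median(np.abs(mat - med), axis=0)
                    curves.append(pd.DataFrame({
                        "channel": channel, "state": state, "phase": phase,
                        "group": grp, "freq_hz": freqs, "median": med, "mad": mad,
                        "n_animals": mat.shape[0]}))
                if A is not None and B is not None and len(A) >= 2 and len(B) >= 2:
                    mask = effect_stats.spectral_auc_mask(
                        A, B, freqs, n_boot=config.n_boot, seed=rng)
                    masks[(channel, state, phase)] = mask
                from ratsleep.spectral import SpectralResult, band_power
                for aid, grp, rel in rows:
                    bp = band_power(SpectralResult(freqs=freqs, power=rel,
                                                   relative=rel),
                                    config.spectral.bands)
                    for band, v in bp.items():
                        band_rows.append({
                            "animal_id": aid, "group": grp, "channel": channel,
                            "state": state, "phase": phase, "band": band,
                            "relative_power": v})
                # entropy of difference per tau
                for tau in config.eod_taus:
                    params = EoDParams(m=config.eod_m, tau=tau)
                    for a in cohort:
                        rec = a.recording_covering(window)
                        if rec is None or a.hyp_micro is None:
                            continue
                        v = eod_by_state(rec, a.hyp_micro, state, window, channel,
                                         params)
                        if isinstance(v, AbsentREM):
                            continue
                        eod_rows.append({"animal_id": a.animal_id, "group": a.group,
                                         "channel": channel, "state": state,
                                         "phase": phase, "tau": tau, "eod": v})
    out: dict = {
        "relpower_curves": (pd.concat(curves, ignore_index=True)
                            if curves else pd.DataFrame()),
        "spectral_masks": masks,
        "band_power": pd.DataFrame(band_rows).drop_duplicates(),
        "eod": pd.DataFrame(eod_rows),
    }
    out["band_effects"] = _band_effects(out["band_power"], config, rng)
    out["eod_effects"] = _eod_effects(out["eod"], config, rng)
    return out


def _band_effects(band_df, config, rng):
    rows = []
    if band_df.empty:
        return pd.DataFrame(rows)
    for (ch, st, ph, band), sub in band_df.groupby(["channel", "state", "phase", "band"]):
        xa = sub[sub["group"] == "AC"]["relative_power"].to_numpy()
        xb = sub[sub["group"] == "AD"]["relative_power"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            continue
        es = effect_stats.bootstrap_auc_ci(xa, xb, n_boot=config.n_boot, seed=rng)
        rows.append({"channel": ch, "state": st, "phase": ph, "band": band,
                     **es.as_dict()})
    return pd.DataFrame(rows)


def _eod_effects(eod_df, config, rng):
    """AUC table: AC vs AD per state, and WAKE vs NREM within each group."""
    rows = []
    if eod_df.empty:
        return pd.DataFrame(rows)
    for (ch, ph, tau), sub in eod_df.groupby(["channel", "phase", "tau"]):
        for state in STATES:
            ss = sub[sub["state"] == state]
            xa = ss[ss["group"] == "AC"]["eod"].to_numpy()
            xb = ss[ss["group"] == "AD"]["eod"].to_numpy()
            if len(xa) >= 2 and len(xb) >= 2:
                es = effect_stats.bootstrap_auc_ci(xa, xb, n_boot=config.n_boot,
                                                   seed=rng)
                rows.append({"comparison": "AC_vs_AD", "channel": ch, "phase": ph,
                             "tau": tau, "state": state, **es.as_dict()})
        for grp in ("AC", "AD"):
            gs = sub[sub["group"] == grp]
            w = gs[gs["state"] == "WAKE"]["eod"].to_numpy()
            n = gs[gs["state"] == "NREM"]["eod"].to_numpy()
            if len(w) >= 2 and len(n) >= 2:
                # oriented so AUC -> 1 means WAKE entropy exceeds NREM entropy
                es = effect_stats.bootstrap_auc_ci(n, w, n_boot=config.n_boot,
                                                   seed=rng)
                rows.append({"comparison": f"WAKE_vs_NREM_{grp}", "channel": ch,
                             "phase": ph, "tau": tau, "state": "", **es.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def run_all(cohort: list[CohortAnimal], config: StudyConfig | None = None,
            out_dir=None) -> dict:
    """Run macro- and microarchitecture analyses; optionally write outputs."""
    config = config or StudyConfig()
    results = {"macro": run_macro(cohort, config), "micro": run_micro(cohort, config)}
    if out_dir is not None:
        write_outputs(results, config, Path(out_dir))
    return results


def write_outputs(results: dict, config: StudyConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    macro, micro = results["macro"], results["micro"]
    for name in ("proportions", "bouts", "bout_tests", "transitions",
                 "transition_effects"):
        macro[name].to_csv(out_dir / f"macro_{name}.csv", index=False)
    with open(out_dir / "macro_anova.json", "w") as fh:
        json.dump(macro["anova"], fh, indent=2)
    for name in ("relpower_curves", "band_power", "band_effects", "eod",
                 "eod_effects"):
        micro[name].to_csv(out_dir / f"micro_{name}.csv", index=False)
    mask_frames = []
    for (ch, st, ph), mask in micro["spectral_masks"].items():
        df = mask.to_frame()
        df.insert(0, "channel", ch)
        df.insert(1, "state", st)
        df.insert(2, "phase", ph)
        mask_frames.append(df)
    (pd.concat(mask_frames, ignore_index=True) if mask_frames
     else pd.DataFrame()).to_csv(out_dir / "micro_spectral_masks.csv", index=False)
    cfg_repr = repr(config).encode()
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "n_boot": config.n_boot,
                   "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
                   "config": repr(config)}, fh, indent=2)
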