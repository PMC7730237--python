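import numpy as np
import pytest

from ratsleep import synthetic_data as sd
from ratsleep.effect_stats import anderson_darling_2samp
from ratsleep.entropy import EoDParams, eod_by_state
from ratsleep.hypnogram_metrics import count_transitions, extract_bouts
from ratsleep.signal_io import EEG_ROSTRAL, EMG, STATES
from ratsleep.spectral import band_power, state_spectrum


def brute_force_proportions(params, n_epochs=2_000_000, epoch_len=4.0, seed=99):
    """Oracle: long-run epoch fractions from a plain-python renewal simulation."""
    rng = np.random.default_rng(seed)
    order = list(STATES)
    state = "WAKE"
    counts = {s: 0 for s in order}
    total = 0
    while total < n_epochs:
        mu = np.log(params.mean_bout[state]) - params.sigma ** 2 / 2
        dur = max(1, round(rng.lognormal(mu, params.sigma) / epoch_len))
        counts[state] += dur
        total += dur
        row = params.transition[state]
        nxt = [s for s in order if s != state]
        state = rng.choice(nxt, p=[row.get(s, 0.0) for s in nxt])
    return {s: counts[s] / total for s in order}


class TestHypnogramSimulation:
    def test_proportions_match_long_run_oracle(self):
        # homogeneous chain (same parameters both phases) so the long-run
        # law is well defined; cohort mean within 2 SE of the oracle
        params = sd.default_phase_params()["inactive"]
        both = {"inactive": params, "active": params}
        oracle = brute_force_proportions(params)
        profile = sd.GroupEffectProfile()
        cfg = sd.SimulationConfig(duration=86400, seed=0)
        props = []
        rng = np.random.default_rng(7)
        for _ in range(200):
            hyp = sd.simulate_hypnogram(cfg, profile, params=both, rng=rng,
                                        epoch_len=cfg.micro_epoch)
            props.append([np.mean(hyp.labels == s) for s in STATES])
        props = np.asarray(props)
        mean, se = props.mean(axis=0), props.std(axis=0) / np.sqrt(len(props))
        for k, s in enumerate(STATES):
            assert abs(mean[k] - oracle[s]) < 2 * se[k] + 0.01, (s, mean[k], oracle[s])

    def test_reduced_nrem_bout_scale_shrinks_bouts(self):
        cfg = sd.SimulationConfig(duration=86400, seed=0)
        base = sd.GroupEffectProfile(bout_jitter=0.0)
        short = sd.GroupEffectProfile(
            bout_scale={"WAKE": 1.0, "NREM": 0.5, "REM": 1.0}, bout_jitter=0.0)
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(2)
        bouts_a, bouts_b = [], []
        for _ in range(20):
            ha = sd.simulate_hypnogram(cfg, base, rng=rng_a)
            hb = sd.simulate_hypnogram(cfg, short, rng=rng_b)
            bouts_a.extend(extract_bouts(ha).query("state == 'NREM'")["duration"])
            bouts_b.extend(extract_bouts(hb).query("state == 'NREM'")["duration"])
        stat, p = anderson_darling_2samp(bouts_a, bouts_b)
        assert p < 0.05
        assert np.median(bouts_b) < np.median(bouts_a)

    def test_degenerate_all_wake_chain(self):
        params = sd.SemiMarkovParams(
            mean_bout={"WAKE": 1e7, "NREM": 10.0, "REM": 10.0},
            transition={"WAKE": {"NREM": 1.0, "REM": 0.0},
                        "NREM": {"WAKE": 1.0, "REM": 0.0},
                        "REM": {"WAKE": 1.0, "NREM": 0.0}})
        cfg = sd.SimulationConfig(duration=86400, seed=5)
        hyp = sd.simulate_hypnogram(cfg, sd.GroupEffectProfile(),
                                    params={"inactive": params, "active": params})
        assert (hyp.labels == "WAKE").all()
        assert count_transitions(hyp).total == 0

    def test_nonstochastic_transition_row_rejected(self):
        params = sd.default_phase_params()
        params["inactive"].transition["WAKE"] = {"NREM": 0.4, "REM": 0.4}
        cfg = sd.SimulationConfig(duration=86400, seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            sd.simulate_hypnogram(cfg, sd.GroupEffectProfile(), params=params)

    def test_deterministic_under_fixed_seed(self):
        cfg = sd.SimulationConfig(duration=86400, seed=42)
        prof = sd.GroupEffectProfile()
        h1 = sd.simulate_hypnogram(cfg, prof)
        h2 = sd.simulate_hypnogram(cfg, prof)
        assert (h1.labels == h2.labels).all()

    def test_stationary_proportions_sum_to_one(self):
        w = sd.stationary_proportions(sd.default_phase_params()["active"])
        assert sum(w.values()) == pytest.approx(1.0)


EEG_WINDOW = (7 * 3600.0, 7 * 3600.0 + 1800.0)


@pytest.fixture(scope="module")
def animal():
    cfg = sd.SimulationConfig(duration=86400, seed=31, eeg_windows=(EEG_WINDOW,))
    prof = sd.GroupEffectProfile(relpower_jitter=0.0, bout_jitter=0.0)
    return sd.simulate_animal(cfg, prof, "AC", "a1", np.random.SeedSequence(3))


class TestEEGSynthesis:
    WINDOW = EEG_WINDOW

    def test_band_limits_respected(self, animal):
        rec = animal.recordings[0]
        from ratsleep.spectral import welch_psd
        for role, hi in ((EEG_ROSTRAL, 30.0), (EMG, 40.0)):
            x = np.asarray(rec.data[role], dtype=float)
            res = welch_psd(x[None, :])
            out = res.power[res.freqs > hi + 2]
            assert out.sum() < 0.01 * res.power.sum()

    def test_nrem_delta_target_round_trip(self):
        # recipe with delta 0.6 and almost no broadband remainder
        cfg = sd.SimulationConfig(duration=7200, seed=13)
        prof = sd.GroupEffectProfile(
            relpower_profile={s: {"delta": 0.60, "theta": 0.20, "alpha": 0.10,
                                  "beta": 0.08} for s in STATES},
            relpower_jitter=0.0, bout_jitter=0.0)
        a = sd.simulate_animal(cfg, prof, "AC", "a", np.random.SeedSequence(8))
        res = state_spectrum(a.recording, a.truth_micro, "NREM", (0.0, 7200.0),
                             EEG_ROSTRAL)
        assert 0.55 <= band_power(res)["delta"] <= 0.65

    def test_generator_targets_recovered_within_tolerance(self, animal):
        rec = animal.recordings[0]
        for state in ("WAKE", "NREM"):
            res = state_spectrum(rec, animal.truth_micro, state, self.WINDOW,
                                 EEG_ROSTRAL)
            expected = sd.expected_band_fractions(sd.DEFAULT_RELPOWER[state])
            measured = band_power(res)
            for b in expected:
                assert abs(measured[b] - expected[b]) < 0.05, (state, b)

    def test_alpha_only_recipe_concentrates_power(self):
        cfg = sd.SimulationConfig(duration=3600, seed=17)
        prof = sd.GroupEffectProfile(
            relpower_profile={s: {"delta": 0.0, "theta": 0.0, "alpha": 0.98,
                                  "beta": 0.0} for s in STATES},
            relpower_jitter=0.0, bout_jitter=0.0)
        a = sd.simulate_animal(cfg, prof, "AC", "a", np.random.SeedSequence(8))
        for state in set(a.truth_micro.labels):
            res = state_spectrum(a.recording, a.truth_micro, str(state),
                                 (0.0, 3600.0), EEG_ROSTRAL)
            bp = band_power(res)
            # edge bins of the 6 Hz wide band capture some leakage, so the
            # realized fraction sits slightly below the 0.98 recipe
            assert bp["alpha"] > 0.8
            assert bp["alpha"] == max(bp.values())

    def test_emg_amplitude_orders_states(self, animal):
        rec = animal.recordings[0]
        hyp = animal.truth_micro
        sel = ((hyp.epoch_zt >= self.WINDOW[0])
               & (hyp.epoch_zt + 4.0 <= self.WINDOW[1]))
        emg = np.asarray(rec.data[EMG], dtype=float)
        rms = {}
        for s in ("WAKE", "NREM"):
            idx = np.flatnonzero(sel & (hyp.labels == s))
            segs = [emg[int((zt - rec.zt_start) * 200):int((zt - rec.zt_start) * 200) + 800]
                    for zt in hyp.epoch_zt[idx]]
            rms[s] = np.sqrt(np.mean(np.concatenate(segs) ** 2))
        assert rms["WAKE"] > 2 * rms["NREM"]

    def test_positive_eod_shift_raises_entropy(self):
        cfg = sd.SimulationConfig(duration=86400, seed=19,
                                  eeg_windows=(self.WINDOW,))
        base = sd.GroupEffectProfile(relpower_jitter=0.0, bout_jitter=0.0)
        shifted = sd.GroupEffectProfile(
            eod_shift={"WAKE": 0.0, "NREM": 0.3, "REM": 0.0},
            relpower_jitter=0.0, bout_jitter=0.0)
        seq = np.random.SeedSequence(4)
        a = sd.simulate_animal(cfg, base, "AC", "a", seq)
        b = sd.simulate_animal(cfg, shifted, "AD", "b", seq)
        p = EoDParams(tau=1)
        ea = eod_by_state(a.recordings[0], a.truth_micro, "NREM", self.WINDOW,
                          EEG_ROSTRAL, p)
        eb = eod_by_state(b.recordings[0], b.truth_micro, "NREM", self.WINDOW,
                          EEG_ROSTRAL, p)
        assert eb > ea

    def test_identical_seed_identical_sample_path(self):
        cfg = sd.SimulationConfig(duration=3600, seed=23)
        prof = sd.GroupEffectProfile()
        a = sd.simulate_animal(cfg, prof, "AC", "a", np.random.SeedSequence(1))
        b = sd.simulate_animal(cfg, prof, "AC", "a", np.random.SeedSequence(1))
        assert np.array_equal(a.recording.data[EEG_ROSTRAL],
                              b.recording.data[EEG_ROSTRAL])

    def test_fs_mismatch_raises(self):
        cfg = sd.SimulationConfig(duration=3600, seed=1)
        hyp_bad = sd.simulate_hypnogram(cfg, sd.GroupEffectProfile(),
                                        epoch_len=10.0)
        hyp_bad = type(hyp_bad)(labels=hyp_bad.labels, epoch_len=0.0301)
        with pytest.raises(ValueError, match="epoch length"):
            sd.simulate_eeg(hyp_bad, sd.GroupEffectProfile(), cfg)


class TestCohort:
    def test_default_cohort_shape(self, small_cohort):
        assert len(small_cohort) == 15
        groups = [a.group for a in small_cohort]
        assert groups.count("AC") == 7 and groups.count("AD") == 8
        for a in small_cohort:
            assert a.truth_macro.duration == 86400.0
            assert a.recordings[0].fs == 200.0

    def test_master_seed_changes_noise_only_in_api_terms(self):
        cfg1 = sd.SimulationConfig(duration=7200, seed=1)
        cfg2 = sd.SimulationConfig(duration=7200, seed=2)
        prof = sd.control_profile()
        c1 = sd.simulate_cohort(cfg1, prof, prof, n_ac=1, n_ad=1)
        c2 = sd.simulate_cohort(cfg2, prof, prof, n_ac=1, n_ad=1)
        assert not np.array_equal(c1[0].recording.data[EEG_ROSTRAL],
                                  c2[0].recording.data[EEG_ROSTRAL])

    def test_rem_deficit_removes_rem(self):
        cfg = sd.SimulationConfig(duration=86400, seed=3)
        prof = sd.GroupEffectProfile(rem_deficit_prob=1.0)
        a = sd.simulate_animal(cfg, prof, "AD", "x", np.random.SeedSequence(0))
        assert "REM" not in set(a.truth_macro.labels)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            sd.GroupEffectProfile(bout_scale={"WAKE": -1.0})
        with pytest.raises(ValueError):
            sd.GroupEffectProfile(transition_rate_scale=0.0)
        with pytest.raises(ValueError):
            sd.GroupEffectProfile(relpower_profile={
                "WAKE": {"delta": 0.9, "theta": 0.9}})
        with pytest.raises(ValueError):
            sd.GroupEffectProfile(rem_deficit_prob=1.5)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="multiple"):
            sd.SimulationConfig(duration=86405.0)
        with pytest.raises(ValueError, match="fs"):
            sd.SimulationConfig(duration=86400, fs=60.0)

    def test_cohort_files_written(self, tmp_path):
        cfg = sd.SimulationConfig(duration=7200, seed=5,
                                  eeg_windows=((0.0, 600.0),))
        prof = sd.control_profile()
        sd.simulate_cohort(cfg, prof, prof, n_ac=1, n_ad=1, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "AC01_hyp10.csv").exists()
        assert (tmp_path / "AD01_rec0.csv").exists()
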