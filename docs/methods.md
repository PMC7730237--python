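# Methods

This note documents the models, parameter defaults and numerical choices
behind `ratsleep`, and what the synthetic-data tests do and do not show
about real recordings.

## Conventions

Zeitgeber time (ZT) is seconds since lights-on. ZT 0–12 h is the inactive
(lights-on) phase for nocturnal rodents, ZT 12–24 h the active phase.
Epoch timestamps are epoch-start times; epochs are half-open intervals
`[start, start + len)`. Hypnograms carry one of three vigilance states per
epoch — WAKE, NREM, REM — at either 10 s (whole-recording "macro" scoring)
or 4 s ("micro" scoring for quantitative EEG). The default quantitative-EEG
analysis windows are ZT 7–9 h (inactive) and ZT 19–21 h (active), which
correspond to 2–4 pm and 2–4 am under lights-on at 7 am.

## Acquisition filter contract

EEG channels are band-limited to 1–30 Hz and EMG to 10–40 Hz. The
`signal_io.bandpass` implementation is a zero-phase (forward–backward)
4th-order Butterworth; the original analog amplification chain's exact
rolloff is unknowable, so only the pass-bands are contractual. Out-of-band
tones are attenuated by more than 20 dB, pass-band tones preserved within
5%, and the filter is linear (superposition holds on test tones).

## Macroarchitecture

* **State proportions**: fraction of epochs per state in consecutive 2 h
  bins (12 bins across 24 h). Group comparison: two-way ANOVA with factors
  group and time (main-effects model, matching the common n-way ANOVA
  default; the interaction is available behind a flag). Post-hoc group
  contrasts per time bin use Welch t-tests at the Dunn–Šidák-adjusted level
  α′ = 1 − (1 − α)^(1/k), k = number of bins.
* **Bouts**: maximal runs of one state. A bout spanning a phase boundary
  belongs to the phase of its first epoch (the simplest deterministic rule;
  it affects at most two bouts per phase per day). Boundary-truncated bouts
  are included by default; `drop_boundary=True` removes the first and last
  bout. Bout-length distributions are summarised as empirical CDFs;
  quantiles (e.g. the duration below which 80% of bouts fall) use linear
  interpolation between order statistics (the numpy default). Group
  comparison: two-sample Anderson–Darling (Scholz–Stephens statistic via
  scipy), with an exact permutation p-value automatically substituted when
  either group has fewer than 5 observations.
* **Transitions**: label changes across the binary WAKE vs {NREM ∪ REM}
  partition; NREM↔REM changes are not transitions. The two directions can
  differ by at most one in any record. Counts are produced on whichever
  epoch basis the supplied hypnogram has; the pipeline reports both the
  12 h phases on the 10 s grid and the analysis windows on the 4 s grid.

## Spectral analysis

Epochs of one state inside an analysis window are pooled; if the state is
REM and the window contains none, the temporally closest REM episode in the
same light/dark phase is substituted, and if the whole phase lacks REM an
explicit absent-REM marker excludes the animal from group statistics for
that state. Welch PSDs use NFFT = 256 at fs = 200 Hz (0.78125 Hz bins),
Hamming window, 50% overlap, with segments taken within each 4 s epoch so
no segment spans the join between non-contiguous pooled epochs; only NFFT
is inherited from the original analysis description, the rest are the
standard pwelch defaults. Spectra are pooled first and normalised once
(relative power = per-bin power / summed power over 1–30 Hz); per-epoch
normalisation is available behind a flag. Band powers sum relative power
over bins whose center lies in half-open intervals — delta [1, 4), theta
[4, 8), alpha [8, 14), beta [14, 30) Hz — so the four bands partition the
normalisation range exactly. The lower delta edge is forced by the 1 Hz
acquisition high-pass and the beta upper edge by the 30 Hz low-pass.

## Entropy of difference

A motif of length m at lag τ starting at sample i is
(x[i], x[i+τ], …, x[i+(m−1)τ]); its sign pattern is the m−1 signs of
consecutive differences. EoD is the Shannon entropy (base 2) of the
empirical sign-pattern distribution; defaults m = 5, τ ∈ {1, 6}. Exact
zero differences map deterministically to "−" (`merge_down`); a
three-symbol variant keeps ties as their own symbol for sensitivity
analysis. Normalised values divide by the maximal attainable entropy
((m−1) bits, or (m−1)·log₂3 under the three-symbol policy) so results lie
in [0, 1] and are comparable across τ; both normalised and raw values can
be exported since the original analysis does not state a normalisation.
In pooled computation, motifs never cross epoch boundaries (pooled epochs
are not contiguous); pattern counts are summed over epochs before the
entropy is taken, so duplicating an epoch leaves the value unchanged.
Because sign patterns depend only on amplitude ordering, EoD is invariant
under strictly increasing transforms. Permutation entropy (rank patterns,
ties broken by position) is provided as a cross-check statistic.

## Effect sizes and tests

The AUC effect size is the Mann–Whitney estimator
(wins + ½·ties)/(n_A·n_B), oriented so values above 0.5 mean the second
(disease) group is stochastically larger. Confidence intervals are
stratified percentile bootstrap (resampling within each group), default
10 000 resamples, seed mandatory in pipeline runs; the CI is clamped to
contain the point estimate so the invariant ci_low ≤ AUC ≤ ci_high holds
even in degenerate resampling corners. A comparison is significant iff the
95% CI excludes 0.5. Magnitudes below 0.5 are mirrored (1 − AUC) before
labelling: ≥ 0.9 excellent/outstanding, ≥ 0.8 good/excellent, ≥ 0.7
fair/acceptable, ≥ 0.6 poor, else none. Across spectral bins the only
multiplicity control is the neighbour rule — a bin is reported only if it
and at least one adjacent bin are individually significant — so the final
mask is a subset of the per-bin significances and consists of runs of
length ≥ 2. Grubbs's outlier test is the iterative one-at-a-time two-sided
variant with the t-distribution critical value. The 2×2 chi-squared is
emitted both with and without Yates continuity correction, since software
defaults differ.

## Synthetic cohort generator

The generator defines the study conditions for all end-to-end tests.

* **Hypnograms**: a phase-dependent semi-Markov chain. Per state, bout
  durations are lognormal (shape σ = 0.8 in log-space; the heavy right
  tail matches how empirical bout-length cumulative curves approach 1
  gradually) with phase-specific means; next states come from a 3×3
  zero-diagonal matrix. REM is entered almost exclusively from NREM
  (WAKE→REM probability 0.05). Defaults (seconds; free choices — the
  original study reports no generative parameters):

  | phase | WAKE | NREM | REM | NREM→REM |
  |---|---|---|---|---|
  | inactive | 90 | 170 | 80 | 0.45 |
  | active | 340 | 100 | 60 | 0.30 |

  giving roughly 50/40/10% WAKE/NREM/REM of the 24 h day. Durations are
  drawn in continuous time, rounded to the 4 s micro grid (so the 4 s truth
  labels tile the bout sequence exactly), and the 10 s macro labels take
  the state at each epoch midpoint, emulating coarse-scoring quantization.
* **EEG**: within each bout, Gaussian noise is spectrally shaped so the
  expected PSD is a sum of flat band components (delta/theta/alpha/beta)
  plus a 1/f broadband floor over 1–30 Hz, with per-state recipes
  (delta-dominant NREM, theta-dominant REM and WAKE). Because the four
  bands tile the whole normalisation range, the floor's power necessarily
  lands inside them; `expected_band_fractions` states the realized
  fractions and is the reference for round-trip checks (generator →
  spectral module agrees within ±0.05 absolute). The two EEG channels use
  the same state recipe with independent noise.
* **EMG**: 10–40 Hz noise with RMS amplitude 1.0 in WAKE, 0.25 in NREM,
  0.08 in REM.
* **Group effects**: multipliers on mean bout duration per state, a global
  transition-rate multiplier (divides all bout means), replacement
  relative-power recipes, an entropy shift per state, and a per-animal
  probability of lacking REM entirely. The entropy shift mixes the state
  PSD toward in-band *white* noise (positive; more uniform sign patterns,
  higher EoD) or toward a slow 1–3 Hz component (negative); a 1/f floor
  alone was found to leave sign-pattern entropy nearly unchanged, since it
  adds almost no high-frequency content. Per-animal biological variability:
  lognormal jitter on bout means (SD 0.15) and additive jitter on band
  targets (SD 0.02, renormalised).
* **Disease-like profile** (`ad_like_profile`): NREM bouts halved, REM
  bouts ×0.7, transition rate ×1.5, power shifted from delta toward theta
  and beta, entropy shifts −0.10 (WAKE) / +0.10 (NREM) / +0.08 (REM), and
  a 20% per-animal chance of no REM. The entropy-shift magnitudes were set
  once, at design time, so the disease analogue's WAKE/NREM entropy
  contrast collapses toward no separation while the control analogue
  separates fully — the qualitative dynamic-range pattern the analysis is
  meant to expose.

What the generator does **not** emulate: movement and electrode artifacts,
inter-channel anatomical differences (rostral theta dominance), circadian
drift within a phase, and any biophysical neural-mass dynamics. Passing
end-to-end tests therefore demonstrates that the analysis recovers effects
of the modelled kinds at realistic sizes — not that it is robust to
artifact-laden real data.

## Scorer

Features per 4 s epoch: periodogram band powers per EEG channel, the
theta/delta ratio (NaN when delta power is zero), and EMG RMS. Decision
rule: EMG RMS above threshold → WAKE (regardless of EEG); else theta/delta
above 2.0 → REM; else NREM. Thresholds are calibrated per recording from
feature percentiles (EMG 60th percentile — placing the cut near the top of
the sleep EMG cluster for an animal that sleeps a little over half the
time — delta 50th; at least ~100 epochs recommended). A single smoothing
pass absorbs one-epoch islands whose two neighbours agree, which cannot
create a state absent before smoothing and leaves two-epoch bouts intact;
the window is deliberately minimal because short bouts are the object of
study. Manual overrides (sparse epoch→state table) apply last. The cited
original routine is not reproduced; this is a transparent replacement whose
error against generator truth is quantified (Cohen's kappa ≥ 0.8 with a
per-state confusion matrix on default profiles).

## Problem sizes and determinism

End-to-end analyses are deterministic given the master seed: per-animal
seeds are spawned from it, and all bootstrap draws flow from the study
seed, so reruns produce byte-identical CSVs. Test and acceptance runs use
24 h hypnograms with EEG synthesised only inside 24–30 min windows per
phase, bootstrap size 2000, 50 seeds for effect-recovery rates, and 2–4
animals for scorer-quality checks; the library defaults remain 10 000
bootstrap resamples and full-duration synthesis.

## Known limitations

* The ANOVA treats cells as independent (animal is not modelled as a
  repeated measure across time bins), matching the n-way ANOVA usage it
  mirrors; a mixed-effects treatment is out of scope.
* Percentile-bootstrap AUC intervals are near-nominal (~94–95% coverage)
  for groups of 30 or more but undercover somewhat (~88–93%) at very small
  group sizes such as 7 vs 8 — the usual small-sample behaviour of the
  percentile method on a bounded statistic. The null significance rate at
  7 vs 8 nevertheless calibrates to ~5%.
* Anderson–Darling p-values from the published interpolation are clipped to
  [0.001, 0.25] by scipy; use the permutation option when exact small
  p-values matter.
* The rostral/caudal channel names are treated as opaque labels; no
  anatomical interpretation is attached.
* Frequencies above 30 Hz are unavailable by construction of the
  acquisition contract.
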