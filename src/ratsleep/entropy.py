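"""Sign-pattern entropy (entropy of difference) and permutation entropy.

The entropy of difference (EoD) reduces an amplitude series to the signs of
the differences between successive values inside lagged motifs: a motif of
length m at lag tau starting at i is (x[i], x[i+tau], ..., x[i+(m-1)tau]);
its sign pattern is the m-1 signs of consecutive differences.  The EoD is
the Shannon entropy of the empirical sign-pattern distribution — maximal for
a uniform pattern distribution, zero when only a single pattern occurs
(e.g. any monotone signal).  Permutation entropy is the analogous statistic
on rank (ordinal) patterns.

Because sign patterns depend only on the ordering of amplitudes, both
statistics are invariant under strictly increasing amplitude transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ratsleep.spectral import AbsentREM, pool_state_epochs


@dataclass
class EoDParams:
    """Entropy-of-difference settings.

    m : motif length (embedding dimension); the default 5 gives 16 binary
        sign patterns.
    tau : lag in samples; 1 probes fast dynamics, 6 slow dynamics at 200 Hz.
    tie_policy : 'merge_down' maps exact zero differences to '-';
        'third_symbol' keeps them as a separate symbol.  Filtered EEG
        essentially never ties, but quantized fixtures can.
    normalize : divide by the maximal attainable entropy so values lie in
        [0, 1] and are comparable across tau.
    """

    m: int = 5
    tau: int = 1
    tie_policy: str = "merge_down"
    normalize: bool = True

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("lag tau must be >= 1")
        if self.tie_policy not in ("merge_down", "third_symbol"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")

    @property
    def span(self) -> int:
        """Number of samples one motif covers: (m-1)*tau + 1."""
        return (self.m - 1) * self.tau + 1

    @property
    def max_entropy_bits(self) -> float:
        n_symbols = 3 if self.tie_policy == "third_symbol" else 2
        return (self.m - 1) * np.log2(n_symbols)


def sign_motifs(x, params: EoDParams) -> np.ndarray:
    """Sign patterns of all motifs of ``x``: array (n_motifs, m-1) of +1/-1 (/0).

    Motif i covers x[i], x[i+tau], ..., x[i+(m-1)tau]; there are
    len(x) - (m-1)*tau motifs.  Under 'merge_down' a zero difference is
    deterministically mapped to -1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (params.m - 1) * params.tau
    if n < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={params.m}, "
            f"tau={params.tau} (needs >= {params.span})")
    diffs = x[params.tau:] - x[:-params.tau]  # sign of x[i+tau] - x[i]
    signs = np.sign(diffs).astype(np.int8)
    if params.tie_policy == "merge_down":
        signs[signs == 0] = -1
    # pattern k of motif i is the sign of the k-th consecutive difference
    idx = np.arange(n)[:, None] + np.arange(params.m - 1)[None, :] * params.tau
    return signs[idx]


def pattern_counts(patterns: np.ndarray) -> np.ndarray:
    """Counts of the distinct rows of a pattern array.

    Rows are encoded as base-3 integers (symbols -1/0/+1 -> digits 0..2) and
    tallied with ``bincount``; only nonzero counts are returned.
    """
    patterns = np.asarray(patterns).astype(np.int64)
    k = patterns.shape[1]
    lo = patterns.min() if patterns.size else 0
    patterns = patterns - lo
    base = int(patterns.max()) + 1 if patterns.size else 1
    weights = base ** np.arange(k, dtype=np.int64)
    codes = patterns @ weights
    counts = np.bincount(codes)
    return counts[counts > 0]


def _shannon_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_of_difference(x, params: EoDParams | None = None) -> float:
    """Shannon entropy (base 2) of the sign-pattern distribution of ``x``.

    Normalised variants divide by (m-1) bits (or (m-1)*log2(3) under the
    third-symbol tie policy) so the value lies in [0, 1]; 0 is attained
    exactly when a single pattern occurs, as for monotone signals.
    """
    params = params or EoDParams()
    h = _shannon_bits(pattern_counts(sign_motifs(x, params)))
    return h / params.max_entropy_bits if params.normalize else h


def eod_from_epochs(epochs: np.ndarray, params: EoDParams | None = None) -> float:
    """EoD over a pool of epochs: motifs never cross epoch boundaries.

    Pooled epochs are not temporally contiguous, so each epoch contributes
    its own motifs; pattern counts are summed over epochs before the entropy
    is taken.  Epochs shorter than one motif span are skipped.
    """
    params = params or EoDParams()
    if isinstance(epochs, np.ndarray) and epochs.dtype != object:
        epochs = np.atleast_2d(epochs)
    all_patterns = []
    for ep in epochs:
        if len(ep) < params.span:
            continue
        all_patterns.append(sign_motifs(ep, params))
    if not all_patterns:
        raise ValueError("no epoch long enough for a single motif")
    h = _shannon_bits(pattern_counts(np.concatenate(all_patterns)))
    return h / params.max_entropy_bits if params.normalize else h


def eod_by_state(recording, hyp, state: str, window, role: str,
                 params: EoDParams | None = None):
    """Per-animal EoD of the pooled epochs of one state within a ZT window.

    Returns a float, or the :class:`AbsentREM` marker when the animal has no
    epoch of the state in the whole phase (the animal is then excluded from
    group statistics).
    """
    pool = pool_state_epochs(recording, hyp, state, window, role)
    if isinstance(pool, AbsentREM):
        return pool
    return eod_from_epochs(pool, params)


def permutation_entropy(x, m: int = 5, tau: int = 1,
                        normalize: bool = True) -> float:
    """Permutation entropy: Shannon entropy of ordinal (rank) patterns.

    The rank pattern of a motif is the argsort of its values (ties broken by
    position, the usual stable convention).  Normalised by log2(m!) so the
    value lies in [0, 1]; a monotone series gives 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(f"series too short for m={m}, tau={tau}")
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * tau
    motifs = x[idx]
    ranks = np.argsort(motifs, axis=1, kind="stable")
    h = _shannon_bits(pattern_counts(ranks))
    if not normalize:
        return h
    return h / np.log2(float(math.factorial(m))) if m > 1 else 0.0
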