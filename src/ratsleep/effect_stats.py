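"""Effect-size and hypothesis-testing layer.

Group comparisons are reported primarily as AUC effect sizes — the
probability that a random draw from the disease group exceeds a random draw
from the control group (ties half-weighted; the Mann-Whitney estimator) —
with bootstrap 95% confidence intervals.  A comparison is significant when
the CI excludes 0.5.  Effect magnitudes below 0.5 are mirrored (1 - AUC),
so an AUC of 0.15 is a good effect of magnitude 0.85.  Spectral per-bin
comparisons additionally require at least two neighbouring significant
frequency bins before a bin is reported (the neighbour rule), which is the
only multiplicity control applied across bins.

Also provided: the two-sample Anderson-Darling test for bout-length
distributions, two-way ANOVA with Dunn-Sidak-corrected post-hoc contrasts
for state proportions, a 2x2 chi-squared for sex counts, and Grubbs's
outlier test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: (threshold on mirrored magnitude, label); traditional academic point system
MAGNITUDE_LABELS = [
    (0.9, "excellent/outstanding"),
    (0.8, "good/excellent"),
    (0.7, "fair/acceptable"),
    (0.6, "poor"),
    (0.0, "none"),
]


def classify_magnitude(auc: float) -> str:
    mag = max(auc, 1.0 - auc)
    for thr, label in MAGNITUDE_LABELS:
        if mag >= thr:
            return label
    return "none"


def auc_effect(group_a, group_b) -> float:
    """Mann-Whitney AUC: P(B > A) + 0.5 P(B = A).

    Orientation is fixed: values above 0.5 mean group B (by convention the
    disease group) is stochastically larger.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = b[None, :] - a[:, None]
    wins = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(wins / (a.size * b.size))


@dataclass
class EffectSize:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool
    magnitude: float
    label: str

    def as_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_boot": self.n_boot, "significant": self.significant,
                "magnitude": self.magnitude, "label": self.label}


def _bootstrap_auc_samples(a: np.ndarray, b: np.ndarray, n_boot: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Stratified bootstrap AUC replicates, vectorised over resamples."""
    na, nb = a.size, b.size
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    diff = b[ib][:, None, :] - a[ia][:, :, None]  # (n_boot, na, nb)
    return ((diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))) / (na * nb)


def bootstrap_auc_ci(group_a, group_b, n_boot: int = 10000,
                     seed: int | np.random.Generator = 0,
                     alpha: float = 0.05) -> EffectSize:
    """AUC with a stratified percentile bootstrap CI.

    Resampling is within each group.  Significance means the CI excludes
    0.5; the magnitude label is assigned from the mirrored point estimate.
    Degenerate resamples (a single distinct value in both groups) yield AUC
    0.5 by the tie convention and need no special handling.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap CI requires at least 2 observations per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = auc_effect(a, b)
    boots = _bootstrap_auc_samples(a, b, n_boot, rng)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, point), max(hi, point)
    return EffectSize(auc=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
                      significant=not (lo <= 0.5 <= hi),
                      magnitude=max(point, 1 - point), label=classify_magnitude(point))


@dataclass
class SpectralAUCMask:
    freqs: np.ndarray
    auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # per-bin CI excludes 0.5
    mask: np.ndarray  # after the two-neighbour rule

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs, "auc": self.auc,
                             "ci_low": self.ci_low, "ci_high": self.ci_high,
                             "significant": self.significant, "masked": self.mask})


def neighbor_rule(significant: np.ndarray) -> np.ndarray:
    """Keep a bin only if it and at least one adjacent bin are significant."""
    sig = np.asarray(significant, dtype=bool)
    if sig.size < 2:
        return np.zeros_like(sig)
    left = np.r_[False, sig[:-1]]
    right = np.r_[sig[1:], False]
    return sig & (left | right)


def spectral_auc_mask(spectra_a: np.ndarray, spectra_b: np.ndarray,
                      freqs: np.ndarray, n_boot: int = 10000,
                      seed: int | np.random.Generator = 0,
                      alpha: float = 0.05) -> SpectralAUCMask:
    """Per-frequency-bin AUC with bootstrap CI and the two-neighbour rule.

    ``spectra_a``/``spectra_b``: arrays (n_animals, n_bins) on a common grid.
    The bootstrap resamples animals; the same resample indices are shared
    across bins, vectorised in chunks.
    """
    A = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    B = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if A.shape[1] != B.shape[1] or A.shape[1] != freqs.size:
        raise ValueError("spectra must share one frequency grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    na, nb, nbins = A.shape[0], B.shape[0], freqs.size
    diff = B[None, :, :] - A[:, None, :]
    point = ((diff > 0).sum(axis=(0, 1)) + 0.5 * (diff == 0).sum(axis=(0, 1))) / (na * nb)
    lo = np.empty(nbins)
    hi = np.empty(nbins)
    chunk = max(1, int(2e7 // (na * nb * nbins)))
    boots = np.empty((n_boot, nbins))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        ia = rng.integers(0, na, size=(k, na))
        ib = rng.integers(0, nb, size=(k, nb))
        d = B[ib][:, None, :, :] - A[ia][:, :, None, :]  # (k, na, nb, nbins)
        boots[done:done + k] = (((d > 0).sum(axis=(1, 2))
                                 + 0.5 * (d == 0).sum(axis=(1, 2))) / (na * nb))
        done += k
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    lo, hi = np.minimum(lo, point), np.maximum(hi, point)
    sig = ~((lo <= 0.5) & (0.5 <= hi))
    return SpectralAUCMask(freqs=freqs, auc=point, ci_low=lo, ci_high=hi,
                           significant=sig, mask=neighbor_rule(sig))


# ---------------------------------------------------------------------------
# distribution and classical tests

def _ad_statistic(a: np.ndarray, b: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.anderson_ksamp([a, b]).statistic)


def anderson_darling_2samp(bouts_a, bouts_b, n_perm: int | None = None,
                           seed: int = 0) -> tuple[float, float]:
    """Two-sample Anderson-Darling test (Scholz-Stephens).

    Returns (statistic, p).  By default the p-value uses the published
    critical-value interpolation (clipped to [0.001, 0.25] by scipy); with
    ``n_perm`` set — recommended for fewer than 5 observations per group —
    an exact permutation p-value of the AD statistic is computed instead.
    """
    a = np.asarray(bouts_a, dtype=float)
    b = np.asarray(bouts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if n_perm is None and min(a.size, b.size) < 5:
        n_perm = 2000
    if n_perm:
        rng = np.random.default_rng(seed)
        stat = _ad_statistic(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if _ad_statistic(pooled[:a.size], pooled[a.size:]) >= stat - 1e-12:
                count += 1
        return stat, (count + 1) / (n_perm + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.anderson_ksamp([a, b])
    return float(res.statistic), float(res.pvalue)


def sidak_alpha(alpha: float, k: int) -> float:
    """Dunn-Sidak familywise-corrected per-comparison level 1-(1-a)^(1/k)."""
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # factor -> sum_sq, df, F, p
    posthoc: pd.DataFrame  # per-time-bin group contrasts, Sidak-adjusted
    alpha_adjusted: float = field(default=np.nan)

    def f_p(self, factor: str) -> tuple[float, float]:
        row = self.table.loc[factor]
        return float(row["F"]), float(row["PR(>F)"])


def proportions_anova(df: pd.DataFrame, value: str = "value",
                      group: str = "group", time: str = "time",
                      alpha: float = 0.05,
                      interaction: bool = False) -> AnovaResult:
    """Two-way ANOVA (factors group x time) on per-animal per-bin values.

    Main-effects model by default, matching the common n-way ANOVA default.
    Post-hoc: per time bin, a group contrast (Welch t) evaluated at the
    Dunn-Sidak-adjusted level across the number of bins.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col, levels in ((group, 2), (time, 2)):
        if df[col].nunique() < levels:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    d = df.rename(columns={value: "_y", group: "_g", time: "_t"})
    formula = "_y ~ C(_g) * C(_t)" if interaction else "_y ~ C(_g) + C(_t)"
    fit = smf.ols(formula, data=d).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index={"C(_g)": group, "C(_t)": time,
                                "C(_g):C(_t)": f"{group}:{time}"})
    bins = sorted(d["_t"].unique())
    a_adj = sidak_alpha(alpha, len(bins))
    rows = []
    glevels = sorted(d["_g"].unique())
    for t in bins:
        sub = d[d["_t"] == t]
        x = sub[sub["_g"] == glevels[0]]["_y"]
        y = sub[sub["_g"] == glevels[1]]["_y"]
        if len(x) > 1 and len(y) > 1:
            tt = stats.ttest_ind(x, y, equal_var=False)
            rows.append({"time": t, "t": tt.statistic, "p": tt.pvalue,
                         "significant": tt.pvalue < a_adj})
    return AnovaResult(table=table, posthoc=pd.DataFrame(rows), alpha_adjusted=a_adj)


def chi2_gender(counts_a, counts_b) -> pd.DataFrame:
    """Chi-squared on a 2x2 contingency table of sex counts per group.

    Returns both the Yates-corrected and the uncorrected statistic side by
    side, since which variant a given software default applies is ambiguous.
    """
    table = np.array([list(counts_a), list(counts_b)], dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    rows = []
    for corrected in (True, False):
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=corrected)
        rows.append({"correction": "yates" if corrected else "none",
                     "chi2": chi2, "p": p, "dof": dof})
    return pd.DataFrame(rows)


def grubbs_test(values, alpha: float = 0.05) -> list[int]:
    """Iterative one-at-a-time Grubbs's outlier test (two-sided).

    Returns indices (into the original array) of detected outliers.  Assumes
    approximate normality of the inlier distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs's test requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no outliers to test")
    idx = np.arange(x.size)
    outliers: list[int] = []
    while x.size >= 3:
        n = x.size
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            break
        g_i = np.abs(x - mean) / sd
        i = int(np.argmax(g_i))
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
        if g_i[i] > g_crit:
            outliers.append(int(idx[i]))
            x = np.delete(x, i)
            idx = np.delete(idx, i)
        else:
            break
    return sorted(outliers)
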