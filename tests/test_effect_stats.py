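import numpy as np
import pytest
from scipy import stats

from ratsleep import effect_stats as es


class TestAUCEffect:
    def test_identical_single_values_all_ties(self):
        assert es.auc_effect([1.0], [1.0]) == 0.5

    def test_complete_separation(self):
        assert es.auc_effect([1, 2, 3], [4, 5, 6]) == 1.0

    def test_interleaved_example(self):
        # pairs: (1,2)+ (1,4)+ (3,2)- (3,4)+ -> 3 wins of 4
        assert es.auc_effect([1, 3], [2, 4]) == 0.75

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            es.auc_effect([], [1.0])

    def test_complement_identity_and_brute_force(self, rng):
        for _ in range(30):
            a = rng.normal(size=rng.integers(2, 51))
            b = rng.normal(size=rng.integers(2, 51))
            auc = es.auc_effect(a, b)
            assert auc + es.auc_effect(b, a) == pytest.approx(1.0)
            wins = sum((y > x) + 0.5 * (y == x) for x in a for y in b)
            assert auc == wins / (len(a) * len(b))

    def test_invariant_under_increasing_transform(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert es.auc_effect(a, b) == es.auc_effect(np.exp(a), np.exp(b))

    def test_agrees_with_mann_whitney_u(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=20)
        u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
        assert es.auc_effect(a, b) == pytest.approx(u / (15 * 20))


class TestMagnitudeLabels:
    @pytest.mark.parametrize("auc,label", [
        (0.95, "excellent/outstanding"), (0.85, "good/excellent"),
        (0.75, "fair/acceptable"), (0.65, "poor"), (0.55, "none"),
        (0.15, "good/excellent"),  # mirrored: 1 - 0.15 = 0.85
        (0.05, "excellent/outstanding"),
    ])
    def test_classification(self, auc, label):
        assert es.classify_magnitude(auc) == label


class TestBootstrapAUC:
    def test_well_separated_groups_significant(self, rng):
        a = rng.normal(0.0, 1.0, size=8)
        b = rng.normal(3.0, 1.0, size=8)
        res = es.bootstrap_auc_ci(a, b, n_boot=2000, seed=1)
        assert res.significant
        assert res.ci_low <= res.auc <= res.ci_high

    def test_mirrored_magnitude(self, rng):
        # groups arranged so the point estimate sits well below 0.5
        a = np.arange(10, dtype=float)
        b = a - 8.2  # only the pair (0, 9) has b > a
        point = es.auc_effect(a, b)
        res = es.bootstrap_auc_ci(a, b, n_boot=500, seed=0)
        assert res.magnitude == pytest.approx(1 - point)

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            es.bootstrap_auc_ci([1.0], [2.0, 3.0], n_boot=100, seed=0)

    def test_ci_coverage_of_true_auc(self):
        # n = 30 per group, normal shift 0.7 SD: true AUC = Phi(0.7/sqrt(2));
        # percentile-bootstrap coverage should be near nominal 95%
        from scipy.stats import norm
        rng = np.random.default_rng(11)
        true_auc = norm.cdf(0.7 / np.sqrt(2))
        cov = 0
        reps = 300
        for _ in range(reps):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30) + 0.7
            r = es.bootstrap_auc_ci(a, b, n_boot=1000, seed=rng)
            cov += r.ci_low <= true_auc <= r.ci_high
        assert 0.92 <= cov / reps <= 0.98

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = es.bootstrap_auc_ci(a, b, n_boot=500, seed=9)
        r2 = es.bootstrap_auc_ci(a, b, n_boot=500, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestSpectralMask:
    def test_neighbor_rule_isolated_bin_removed(self):
        sig = np.array([False, True, False, True, True, True, False])
        mask = es.neighbor_rule(sig)
        assert mask.tolist() == [False, False, False, True, True, True, False]

    def test_mask_subset_of_significance(self, rng):
        A = rng.normal(size=(7, 20))
        B = rng.normal(size=(8, 20))
        B[:, 5:8] += 3.0
        res = es.spectral_auc_mask(A, B, np.arange(20.0), n_boot=1000, seed=0)
        assert not np.any(res.mask & ~res.significant)
        runs = np.diff(np.flatnonzero(np.r_[True, np.diff(
            np.flatnonzero(res.mask)) > 1, True])) if res.mask.any() else []
        assert all(r >= 2 for r in runs)

    def test_injected_contrast_detected_in_right_bins(self, rng):
        A = rng.normal(0, 0.05, size=(7, 15)) + 0.5
        B = rng.normal(0, 0.05, size=(8, 15)) + 0.5
        B[:, 6:9] += 0.4  # strong difference in bins 6-8
        res = es.spectral_auc_mask(A, B, np.arange(15.0), n_boot=1000, seed=2)
        assert res.mask[6:9].all()
        assert res.mask.sum() <= 5  # little outside the injected bins

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="grid"):
            es.spectral_auc_mask(rng.normal(size=(4, 10)),
                                 rng.normal(size=(4, 11)), np.arange(10.0))


class TestAndersonDarling:
    def test_identical_samples_permutation_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, p = es.anderson_darling_2samp(a, a, n_perm=500)
        assert p > 0.5

    def test_shifted_lognormal_rejected(self, rng):
        a = rng.lognormal(3.0, 1.0, size=100)
        b = rng.lognormal(3.0 - np.log(2), 1.0, size=100)  # half-mean
        stat, p = es.anderson_darling_2samp(a, b)
        assert p < 0.05

    def test_small_samples_use_permutation(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        stat, p = es.anderson_darling_2samp(a, b, seed=3)
        assert 0.0 < p <= 1.0

    def test_tiny_input_raises(self):
        with pytest.raises(ValueError):
            es.anderson_darling_2samp([1.0], [1.0, 2.0])


class TestAnova:
    def test_sidak_closed_form(self):
        assert es.sidak_alpha(0.05, 12) == pytest.approx(1 - 0.95 ** (1 / 12))

    def _frame(self, means, noise, rng, n=3):
        import pandas as pd
        rows = []
        for (g, t), mu in means.items():
            for _ in range(n):
                rows.append({"group": g, "time": t,
                             "value": mu + noise * rng.normal()})
        return pd.DataFrame(rows)

    def test_duplicated_groups_give_zero_f(self, rng):
        import pandas as pd
        # AD values are an exact copy of AC values -> group SS is exactly 0
        rows = []
        for t in (0, 1):
            vals = rng.normal(size=3)
            for g in ("AC", "AD"):
                rows += [{"group": g, "time": t, "value": v} for v in vals]
        res = es.proportions_anova(pd.DataFrame(rows))
        assert res.f_p("group")[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_matches_hand_computed_sums_of_squares(self, rng):
        df = self._frame({("AC", 0): 1.0, ("AC", 1): 2.0,
                          ("AD", 0): 3.0, ("AD", 1): 5.0}, 0.5, rng)
        res = es.proportions_anova(df)
        # hand computation: main-effects ANOVA on a balanced 2x2 layout
        y = df["value"].to_numpy()
        g = (df["group"] == "AD").to_numpy().astype(float)
        t = (df["time"] == 1).to_numpy().astype(float)
        grand = y.mean()
        ss_g = sum(len(y[g == v]) * (y[g == v].mean() - grand) ** 2 for v in (0, 1))
        ss_t = sum(len(y[t == v]) * (y[t == v].mean() - grand) ** 2 for v in (0, 1))
        # balanced layout: residual SS = total SS minus both main effects
        ss_e = np.sum((y - grand) ** 2) - ss_g - ss_t
        f_g = (ss_g / 1) / (ss_e / (len(y) - 3))
        assert res.f_p("group")[0] == pytest.approx(f_g, rel=1e-6)
        assert res.table.loc["time", "F"] == pytest.approx(
            (ss_t / 1) / (ss_e / (len(y) - 3)), rel=1e-6)

    def test_single_level_factor_raises(self, rng):
        df = self._frame({("AC", 0): 1.0, ("AC", 1): 2.0}, 0.1, rng)
        with pytest.raises(ValueError, match="levels"):
            es.proportions_anova(df)


class TestChi2:
    def test_equal_distributions(self):
        res = es.chi2_gender((5, 5), (5, 5))
        row = res[res["correction"] == "none"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_closed_form_2x2(self):
        a, b, c, d = 3, 4, 2, 6
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = es.chi2_gender((a, b), (c, d))
        assert res[res["correction"] == "none"]["chi2"].iloc[0] \
            == pytest.approx(expected)
        yates = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert res[res["correction"] == "yates"]["chi2"].iloc[0] \
            == pytest.approx(yates)

    def test_perfect_association(self):
        res = es.chi2_gender((10, 0), (0, 10))
        assert (res["p"] < 0.001).all()

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            es.chi2_gender((0, 5), (0, 5))


class TestGrubbs:
    def test_flags_gross_outlier(self):
        assert es.grubbs_test([1.0, 1.1, 0.9, 10.0]) == [3]

    def test_clean_normal_sample_unflagged(self, rng):
        x = rng.standard_normal(20)
        x = (x - x.mean()) / x.std()  # no gross outlier by construction
        assert es.grubbs_test(x, alpha=0.01) == []

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            es.grubbs_test([1.0, 2.0])

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant"):
            es.grubbs_test([2.0, 2.0, 2.0, 2.0])
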