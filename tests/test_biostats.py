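"""Paired-comparison routing, ICC(A,1), and paired-t sample size."""

import numpy as np
import pytest
from scipy import stats

from archpwv import (DegenerateDataError, icc_a1, paired_compare,
                     sample_size_paired_t)


def icc_a1_bruteforce(x):
    """Direct variance-components oracle from the sum-of-squares definitions."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((v - grand) ** 2 for v in x.ravel())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestPairedCompare:
    def test_identical_vectors_degenerate_p_one(self):
        res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_used == "degenerate"
        assert res.p_value == 1.0

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_compare([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_forced_paired_t_hand_computation(self):
        # differences (1, 1, 2): t = 4.00, df = 2, two-sided p = 0.0572
        res = paired_compare([1, 2, 3], [2, 3, 5], test="paired_t")
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.0572, abs=2e-4)
        # closed form for df = 2: P(|T| > t) = 1 - t/sqrt(2 + t^2)
        assert res.p_value == pytest.approx(1 - 4 / np.sqrt(18), abs=1e-12)

    def test_auto_routing_follows_shapiro(self):
        # (1, 1, 2) with a tie at n = 3 fails Shapiro-Wilk -> Wilcoxon
        res = paired_compare([1, 2, 3], [2, 3, 5])
        assert res.normality_p < 0.05
        assert res.test_used == "wilcoxon"
        # clearly normal-looking differences -> paired t
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        res2 = paired_compare(a, a + rng.normal(0.5, 1, 20))
        assert res2.test_used == "paired_t"

    def test_wilcoxon_branch_matches_scipy_exact(self):
        a = np.arange(10.0)
        b = a + np.array([3, -1, 2, 5, -2.5, 4, 1.5, -3.5, 6, 0.5])
        res = paired_compare(a, b, test="wilcoxon")
        ref = stats.wilcoxon(b - a, zero_method="wilcox", correction=True,
                             method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_null_type_i_error_scaled_monte_carlo(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, 24)
            b = a + rng.normal(0, 1, 24)
            if paired_compare(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])


class TestICC:
    def test_perfect_agreement(self):
        res = icc_a1([[1, 1], [2, 2], [3, 3], [4, 4]])
        assert res.icc == pytest.approx(1.0)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_hand_anova(self):
        res = icc_a1([[1, 2], [2, 3], [3, 4], [4, 5]])
        assert res.ms_rows == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert res.ms_cols == pytest.approx(2.0, abs=1e-12)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)
        assert res.icc == pytest.approx(10.0 / 13.0, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_a1([[2.0, 2.0], [2.0, 2.0]])

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, (5, 2)) + rng.normal(0, 2, (5, 1))
            assert icc_a1(x).icc == pytest.approx(icc_a1_bruteforce(x),
                                                  abs=1e-10)

    def test_matches_pingouin_value_and_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x = rng.normal(0, 1, (12, 3)) + rng.normal(0, 2, (12, 1))
        n, k = x.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": x.ravel()})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        res = icc_a1(x)
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        # pingouin prints the CI rounded to 2 decimals
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_ci_coverage_near_nominal(self):
        # true reliability 0.95, n = 24 subjects, 2 raters
        rng = np.random.default_rng(99)
        true_icc = 0.95
        sigma_s, sigma_e = 1.0, np.sqrt((1 - true_icc) / true_icc)
        hits, reps = 0, 300
        for _ in range(reps):
            subj = rng.normal(0, sigma_s, (24, 1))
            x = subj + rng.normal(0, sigma_e, (24, 2))
            lo, hi = icc_a1(x).ci95
            hits += lo <= true_icc <= hi
        assert hits / reps >= 0.90


class TestSampleSize:
    def test_monotone_in_effect_size(self):
        assert sample_size_paired_t(0.5) > sample_size_paired_t(1.0)

    def test_monotone_in_alpha_and_power(self):
        assert sample_size_paired_t(0.8, alpha=0.01) \
            >= sample_size_paired_t(0.8, alpha=0.05)
        assert sample_size_paired_t(0.8, power=0.99) \
            >= sample_size_paired_t(0.8, power=0.80)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestPower
        for d in (0.8, 1.0, 1.3):
            n = sample_size_paired_t(d, alpha=0.05, power=0.95)
            n_sm = int(np.ceil(TTestPower().solve_power(
                effect_size=d, alpha=0.05, power=0.95,
                alternative="two-sided")))
            assert n == n_sm

    def test_monte_carlo_power_at_returned_n(self):
        d = 1.3
        n = sample_size_paired_t(d, alpha=0.05, power=0.95)
        rng = np.random.default_rng(5)
        reps, hits = 3000, 0
        for _ in range(reps):
            diffs = rng.normal(d, 1.0, n)
            if stats.ttest_1samp(diffs, 0.0).pvalue < 0.05:
                hits += 1
        assert hits / reps >= 0.93  # achieved power ~>= nominal 0.95

    def test_effect_size_interval_for_n_equal_10_nonempty(self):
        # some plausible effect size must reproduce the protocol's n = 10
        grid = np.arange(1.0, 1.6, 0.01)
        ns = {d: sample_size_paired_t(d, 0.05, 0.95) for d in grid}
        assert 10 in ns.values()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_paired_t(-1.0)
        with pytest.raises(ValueError):
            sample_size_paired_t(1.0, alpha=1.5)
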