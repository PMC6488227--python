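"""Percent input, ddCt fold changes, exact Mann-Whitney and Pearson r."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import mann_whitney_bruteforce
from mirspan import (ChipMeasurement, QpcrMeasurement, ValidationError,
                     chip_percent_input_summary, ddct_fold, mann_whitney_exact,
                     pearson_r, percent_input, qpcr_fold_summary,
                     relative_expression)


def _chip(ct_ip, ct_input, fraction=0.1):
    return ChipMeasurement("s1", "ZEB1", "promoter", ct_ip, ct_input, fraction)


class TestPercentInput:
    def test_identity_case(self):
        assert percent_input(_chip(30.0, 30.0, fraction=1.0)) == 100.0

    def test_dilution_adjustment_cancels(self):
        ct_ip = 30.0 - np.log2(10.0)
        assert percent_input(_chip(ct_ip, 30.0)) == pytest.approx(100.0,
                                                                  rel=1e-12)

    def test_closed_form_forty_percent(self):
        assert percent_input(_chip(28.0, 30.0)) == pytest.approx(40.0,
                                                                 rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(10, 35), st.floats(-5, 5),
           st.floats(0.01, 1.0), st.floats(-3, 3))
    def test_invariant_to_common_ct_shift(self, ct_input, diff, fraction, shift):
        a = percent_input(_chip(ct_input + diff, ct_input, fraction))
        b = percent_input(_chip(ct_input + diff + shift, ct_input + shift,
                                fraction))
        assert a == pytest.approx(b, rel=1e-9)

    def test_bad_input_fraction_fatal(self):
        with pytest.raises(ValidationError):
            _chip(28.0, 30.0, fraction=0.0)
        with pytest.raises(ValidationError):
            _chip(28.0, 30.0, fraction=1.5)


class TestDdct:
    def test_equal_cts_give_unity(self):
        m = QpcrMeasurement("s", "g", 20.0, 20.0)
        assert relative_expression(m) == 1.0

    def test_group_mean_difference(self):
        a = [QpcrMeasurement("a1", "A", 25.0, 20.0)]  # dCt 5
        b = [QpcrMeasurement("b1", "B", 24.0, 20.0)]  # dCt 4
        assert ddct_fold(a, b) == pytest.approx(0.5)

    def test_empty_group_fatal(self):
        with pytest.raises(ValidationError):
            ddct_fold([], [QpcrMeasurement("b", "B", 24.0, 20.0)])

    def test_recovers_planted_twofold_difference(self):
        from mirspan import SyntheticConfig, simulate_assays

        cfg = SyntheticConfig(rng_seed=5, qpcr_n_per_group=20,
                              qpcr_noise_sd=0.2, qpcr_fold=2.0)
        _, qpcr, _ = simulate_assays(cfg)
        summary = qpcr_fold_summary(qpcr)
        fold = float(summary.loc[0, "fold_a_vs_b"])
        assert 1.8 <= fold <= 2.2


class TestMannWhitneyExact:
    def test_complete_separation(self):
        u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(2 / 20)

    def test_identical_single_values(self):
        u, p = mann_whitney_exact([1.0], [1.0])
        assert u == 0.5 and p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_five_vs_five_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5).round(1)  # rounding induces occasional ties
        y = rng.normal(size=5).round(1)
        res = mann_whitney_exact(x, y)
        u_ref, p_ref = mann_whitney_bruteforce(x, y)
        assert res.u == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)
        assert not res.approximate

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=1, max_size=5),
           st.lists(st.integers(0, 6), min_size=1, max_size=5))
    def test_symmetry_under_group_swap(self, x, y):
        a = mann_whitney_exact(x, y)
        b = mann_whitney_exact(y, x)
        assert a.u + b.u == pytest.approx(len(x) * len(y))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_large_groups_use_flagged_approximation(self):
        rng = np.random.default_rng(0)
        res = mann_whitney_exact(rng.normal(size=60), rng.normal(size=60))
        assert res.approximate
        assert 0 < res.p_value <= 1

    def test_agrees_with_scipy_exact_when_no_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=7)
        res = mann_whitney_exact(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_empty_group_fatal(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([], [1.0])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-2 * v + 7 for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_and_short_input_fatal(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError):
            pearson_r([1, 2], [1, 2])


class TestAssayTables:
    def test_chip_summary_recovers_planted_enrichment_noiselessly(self):
        from mirspan import SyntheticConfig, simulate_assays

        cfg = SyntheticConfig(rng_seed=0, chip_noise_sd=0.0,
                              chip_effect_log2=2.0)
        chip, _, effects = simulate_assays(cfg)
        summary = chip_percent_input_summary(chip)
        zeb1 = summary[(summary["antibody"] == "ZEB1")
                       & (summary["region"] == "promoter")].iloc[0]
        # emitted Ct values are rounded to 6 decimals, hence rel=1e-5
        assert zeb1["mean_percent_input_BAV"] == pytest.approx(
            effects["chip_planted_percent_promoter_zeb_bav"], rel=1e-5)
        assert zeb1["mean_percent_input_TAV"] == pytest.approx(
            effects["chip_baseline_percent"], rel=1e-5)
        igg = summary[(summary["antibody"] == "IGG")
                      & (summary["region"] == "promoter")].iloc[0]
        assert igg["mean_percent_input_BAV"] == pytest.approx(
            igg["mean_percent_input_TAV"], rel=1e-5)

    def test_null_chip_type_one_error_matches_discrete_exact_size(self):
        """At N=5 per group the exact two-sided test's true size at the 0.05
        level is 8/252; the simulated null rejection rate over 600 replicates
        stays within 4 binomial sds of it."""
        rng = np.random.default_rng(11)
        n_rep, n = 600, 5
        rejections = 0
        for _ in range(n_rep):
            x, y = rng.normal(size=n), rng.normal(size=n)
            if mann_whitney_exact(x, y).p_value < 0.05:
                rejections += 1
        size = 8 / 252
        sd = np.sqrt(size * (1 - size) / n_rep)
        assert abs(rejections / n_rep - size) <= 4 * sd
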