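from itertools import combinations

import numpy as np
import pytest

from dpsyntest.dp_mw import u_statistic
from dpsyntest.histograms import TwoGroupSample
from dpsyntest.stat_tests import (
    ContingencyTable2x2,
    check_feasibility,
    chi_squared_test,
    contingency_from_sample,
    median_table,
    median_test,
    mw_u_test,
    run_test,
    t_test,
)


def exact_mw_p(x, y):
    """Two-sided permutation p-value by enumerating every split of the
    pooled values into groups of the observed sizes (tie-free inputs)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mid = n1 * len(y) / 2
    obs = abs(u_statistic(x, y) - mid)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_statistic(xs, ys) - mid) >= obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_do_not_reject(self):
        res = mw_u_test([1, 2, 3], [3, 1, 2])
        assert res.feasible and res.p_value >= 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("sizes, tol", [((3, 3), 0.04), ((4, 4), 0.04),
                                            ((5, 5), 0.02), ((6, 6), 0.02)])
    def test_close_to_exact_permutation_p(self, seed, sizes, tol):
        # worst-case gap of the continuity-corrected normal approximation,
        # by full enumeration: 0.0375 at 3v3, 0.0305 at 4v4, <0.02 from 5v5
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, sizes[0])
        y = r.normal(0.8, 1, sizes[1])
        res = mw_u_test(x, y)
        assert abs(res.p_value - exact_mw_p(x, y)) <= tol

    def test_statistic_is_the_less_than_count(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=7)
        assert mw_u_test(x, y).statistic == pytest.approx(u_statistic(x, y))

    def test_all_tied_values_infeasible(self):
        res = mw_u_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert not res.feasible and res.infeasibility_reason == "all_values_tied"


class TestTTest:
    def test_identical_means(self):
        res = t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_zero_variance_infeasible(self):
        res = t_test([0, 0], [1, 1])
        assert not res.feasible and res.infeasibility_reason == "zero_variance"

    def test_pooled_variance_worked_example(self):
        # means 2.5 vs 4.5, pooled s^2 = 5/3, df = 6
        res = t_test([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.191, abs=1e-3)
        assert res.p_value == pytest.approx(0.0710, abs=1e-3)

    def test_tiny_groups_infeasible(self):
        assert not t_test([1.0], [2.0, 3.0]).feasible

    def test_welch_flag(self):
        res = t_test([1, 2, 3, 4], [3, 4, 5, 6], welch=True)
        assert res.feasible and 0 < res.p_value < 1


class TestMedianTest:
    def test_all_values_tie_grand_median_infeasible(self):
        res = median_test([1, 1, 1], [1, 1, 1])
        assert not res.feasible

    def test_grand_median_table(self):
        table = median_table([1, 2, 3, 4], [5, 6, 7, 8])
        assert (table.a, table.b, table.c, table.d) == (0, 4, 4, 0)

    def test_symmetric_under_group_swap(self, rng):
        x, y = rng.normal(size=15), rng.normal(1, 1, size=12)
        assert median_test(x, y).p_value == pytest.approx(median_test(y, x).p_value)


class TestChiSquared:
    def test_perfect_independence(self):
        res = chi_squared_test(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_yates_worked_example(self):
        # (|ad-bc| - n/2)^2 * n / (row and column products)
        table = ContingencyTable2x2(20, 5, 5, 20)
        assert chi_squared_test(table, yates=False).statistic == pytest.approx(18.0, abs=1e-3)
        assert chi_squared_test(table).statistic == pytest.approx(15.68, abs=1e-3)

    def test_invariant_under_transposition(self):
        t1 = ContingencyTable2x2(7, 3, 2, 9)
        t2 = ContingencyTable2x2(7, 2, 3, 9)
        assert chi_squared_test(t1).statistic == pytest.approx(chi_squared_test(t2).statistic)

    def test_zero_marginal_infeasible(self):
        res = chi_squared_test(ContingencyTable2x2(0, 5, 0, 7))
        assert not res.feasible and res.infeasibility_reason == "zero_marginal"

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestFeasibilityRules:
    def test_single_class_dataset_infeasible_for_all_tests(self):
        s = TwoGroupSample(np.zeros(20, int), np.arange(20.0))
        for name in ("mwu", "ttest", "median", "chi2"):
            feasible, reason = check_feasibility(s, name)
            assert not feasible and reason == "empty_group"

    def test_size_rules_differ_between_tests(self):
        s = TwoGroupSample([0, 1], [1.0, 2.0])
        assert check_feasibility(s, "mwu")[0]
        assert not check_feasibility(s, "ttest")[0]

    def test_constant_values_break_median_and_t(self):
        s = TwoGroupSample([0, 0, 1, 1], [3.0, 3.0, 3.0, 3.0])
        assert not check_feasibility(s, "median")[0]
        assert not check_feasibility(s, "ttest")[0]

    def test_binary_contingency_construction(self):
        s = TwoGroupSample([0, 0, 1, 1], [0.0, 1.0, 1.0, 1.0])
        t = contingency_from_sample(s)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 2)
        with pytest.raises(ValueError):
            contingency_from_sample(TwoGroupSample([0, 1, 0], [0.0, 1.0, 2.0]))


class TestCalibrationUnderNull:
    def test_rejection_rates_at_most_alpha(self):
        """Raw null Gaussian data: every feasible test is valid at alpha=0.05;
        the rank and t tests are also exact (two-sided check), while the
        Yates-corrected tests are conservative (upper bound only)."""
        alpha, reps, n = 0.05, 1000, 100
        rng = np.random.default_rng(99)
        rej = {"mwu": 0, "ttest": 0, "median": 0}
        for _ in range(reps):
            s = TwoGroupSample(
                np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)],
                rng.normal(50, 2, n),
            )
            for name in rej:
                if run_test(s, name).rejects(alpha):
                    rej[name] += 1
        slack = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        for name, count in rej.items():
            assert count / reps <= alpha + slack, name
        for name in ("mwu", "ttest"):
            assert rej[name] / reps >= alpha - slack, name

    def test_chi2_valid_on_null_binary_data(self):
        alpha, reps, n = 0.05, 1000, 200
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(reps):
            s = TwoGroupSample(
                np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)],
                rng.binomial(1, 0.3, n).astype(float),
            )
            if run_test(s, "chi2").rejects(alpha):
                rejections += 1
        assert rejections / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
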