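"""The four non-private independent-sample tests, with explicit feasibility.

Each test returns a :class:`TestResult` instead of raising on degenerate
input: DP synthesizers routinely emit samples on which a test is undefined
(an empty group, all values tied, a zero table marginal), and the
evaluation harness must count those repetitions as infeasible rather than
crash or silently report a p-value.

The p-values themselves come from scipy: the Mann–Whitney U test uses the
asymptotic normal approximation with tie and continuity corrections at all
sample sizes (no exact-method switching), the t-test is the classic
pooled-variance form (Welch optional), and 2x2 chi-squared applies the
Yates continuity correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .histograms import TwoGroupSample

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "mw_u_test",
    "t_test",
    "median_test",
    "chi_squared_test",
    "check_feasibility",
    "contingency_from_sample",
    "run_test",
    "TEST_NAMES",
]

TEST_NAMES = ("mwu", "ttest", "median", "chi2")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test on one dataset."""

    statistic: float
    p_value: float
    test_name: str
    feasible: bool = True
    infeasibility_reason: str = ""

    def __post_init__(self) -> None:
        if self.feasible and not (0 <= self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def rejects(self, alpha: float) -> bool:
        """Strict-inequality rejection rule; infeasible results never reject."""
        return self.feasible and self.p_value < alpha


def _infeasible(test_name: str, reason: str) -> TestResult:
    return TestResult(np.nan, np.nan, test_name, feasible=False, infeasibility_reason=reason)


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def mw_u_test(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test (asymptotic, tie- and continuity-corrected).

    The reported statistic is the U of the first group counted as the
    number of (x_i, y_j) pairs with x_i < y_j, ties as one half — i.e. the
    statistic the DP variant privatizes.
    """
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        return _infeasible("mwu", "empty_group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return _infeasible("mwu", "all_values_tied")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    # scipy reports U of x counted as #{x > y}; convert to the #{x < y} form
    u_less = x.size * y.size - float(res.statistic)
    return TestResult(u_less, float(res.pvalue), "mwu")


def t_test(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test, pooled variance by default."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        return _infeasible("ttest", "empty_group")
    if x.size < 2 or y.size < 2:
        return _infeasible("ttest", "group_too_small")
    if np.var(x) == 0 and np.var(y) == 0:
        return _infeasible("ttest", "zero_variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.pvalue), "ttest")


def median_test(x, y) -> TestResult:
    """Mood's median test: 2x2 table of group vs above/not-above the grand
    median (ties count as not-above), then Yates-corrected chi-squared."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        return _infeasible("median", "empty_group")
    grand = np.median(np.concatenate([x, y]))
    table = ContingencyTable2x2(
        int(np.sum(x > grand)), int(np.sum(x <= grand)),
        int(np.sum(y > grand)), int(np.sum(y <= grand)),
    )
    inner = chi_squared_test(table)
    if not inner.feasible:
        return _infeasible("median", "degenerate_median_table")
    return TestResult(inner.statistic, inner.p_value, "median")


def median_table(x, y) -> ContingencyTable2x2:
    """The grand-median 2x2 table the median test is built on."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    grand = np.median(np.concatenate([x, y]))
    return ContingencyTable2x2(
        int(np.sum(x > grand)), int(np.sum(x <= grand)),
        int(np.sum(y > grand)), int(np.sum(y <= grand)),
    )


def chi_squared_test(table: ContingencyTable2x2, yates: bool = True) -> TestResult:
    """Pearson chi-squared on a 2x2 table, Yates-corrected by default, df=1."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return _infeasible("chi2", "zero_marginal")
    res = stats.chi2_contingency(arr, correction=yates)
    return TestResult(float(res.statistic), float(res.pvalue), "chi2")


def contingency_from_sample(sample: TwoGroupSample) -> ContingencyTable2x2:
    """Group x binary-value table for the chi-squared path.

    The sample's values must take at most two distinct levels (e.g. a 0/1
    medication flag); with a single level the table has a zero column and
    the test will report infeasible.
    """
    levels = np.unique(sample.values)
    if levels.size > 2:
        raise ValueError(f"chi-squared path needs a binary value column, got {levels.size} levels")
    ref = levels[0]
    x, y = sample.group(0), sample.group(1)
    return ContingencyTable2x2(
        int(np.sum(x == ref)), int(np.sum(x != ref)),
        int(np.sum(y == ref)), int(np.sum(y != ref)),
    )


def run_test(sample: TwoGroupSample, test_name: str, **opts) -> TestResult:
    """Dispatch a named test on a two-group sample."""
    if test_name not in TEST_NAMES:
        raise ValueError(f"unknown test {test_name!r}; expected one of {TEST_NAMES}")
    x, y = sample.group(0), sample.group(1)
    if test_name == "mwu":
        return mw_u_test(x, y)
    if test_name == "ttest":
        return t_test(x, y, **opts)
    if test_name == "median":
        return median_test(x, y)
    if x.size == 0 or y.size == 0:
        return _infeasible("chi2", "empty_group")
    try:
        table = contingency_from_sample(sample)
    except ValueError as exc:
        return _infeasible("chi2", str(exc))
    return chi_squared_test(table, **opts)


def check_feasibility(sample: TwoGroupSample, test_name: str) -> tuple[bool, str]:
    """Whether a test's requirements hold on a sample, with a machine-readable
    reason.  Mirrors the per-test rules without computing the p-value."""
    result = run_test(sample, test_name)
    return result.feasible, result.infeasibility_reason
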