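import itertools

import numpy as np
import pytest
from scipy import stats

from dpsyntest.histograms import (
    GAUSSIAN_BINS,
    BinSpec,
    JointHistogram,
    build_joint_histogram,
)
from dpsyntest.generators import GaussianSpec, gaussian_two_group
from dpsyntest.synthesizers import (
    MWEMState,
    PrivacyBudget,
    marginal_workload,
    mwem_fit,
    mwem_sample,
    mwem_synthesize,
    perturbed_histogram_synthesize,
    sample_discrete_laplace,
    smoothed_histogram_probs,
    smoothed_histogram_synthesize,
)

SPEC4 = BinSpec(4, 0, 4)


def _hist(counts):
    counts = np.asarray(counts)
    return JointHistogram(counts, BinSpec(counts.shape[1], 0, counts.shape[1]))


class TestDiscreteLaplace:
    def test_invalid_scale(self, rng):
        with pytest.raises(ValueError):
            sample_discrete_laplace(0.0, rng)

    def test_pmf_matches_two_sided_geometric(self, rng):
        # scipy's dlaplace(a) has pmf tanh(a/2) e^{-a|k|}, i.e. scale b = 1/a
        b = 1.0
        draws = sample_discrete_laplace(b, rng, size=200_000)
        ks = np.arange(-5, 6)
        emp = np.array([(draws == k).mean() for k in ks])
        expected = stats.dlaplace.pmf(ks, 1.0 / b)
        assert np.abs(emp - expected).max() < 0.005
        # closed form at zero: (1-t)/(1+t), t = e^{-1}
        assert expected[5] == pytest.approx((1 - np.e**-1) / (1 + np.e**-1), abs=1e-12)

    def test_symmetric_mean_zero(self, rng):
        draws = sample_discrete_laplace(2.0, rng, size=100_000)
        t = np.exp(-0.5)
        sd = np.sqrt(2 * t / (1 - t) ** 2)
        assert abs(draws.mean()) < 3 * sd / np.sqrt(draws.size)

    def test_small_scale_concentrates_at_zero(self, rng):
        draws = sample_discrete_laplace(0.05, rng, size=10_000)
        assert (draws == 0).mean() > 0.999


class TestPerturbedHistogram:
    def test_no_noise_limit_recovers_counts(self, rng):
        h = _hist([[5, 3, 0, 2], [1, 0, 4, 0]])
        out = perturbed_histogram_synthesize(h, PrivacyBudget(1e6), rng)
        back = build_joint_histogram(out.sample, h.bin_spec)
        assert np.array_equal(back.counts, h.counts)

    def test_requires_pure_epsilon_budget(self, rng):
        with pytest.raises(ValueError):
            perturbed_histogram_synthesize(_hist([[1, 0], [0, 0]]), PrivacyBudget(1, 1e-6), rng)

    def test_zero_clipping_inflates_sparse_histograms(self, rng):
        # a single occupied cell among many empties: clipping empty cells at
        # zero keeps only their positive noise, so E[synthetic size] >= n
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 0] = 20
        h = _hist(counts)
        sizes = [
            perturbed_histogram_synthesize(h, PrivacyBudget(0.1), rng).sample.n
            for _ in range(2000)
        ]
        assert np.mean(sizes) >= h.n

    @pytest.mark.parametrize("epsilon", [0.5, 1.0, 2.0])
    def test_dp_ratio_of_pre_clip_noise_vector(self, epsilon):
        # neighboring (replace-one) 2-cell histograms; outcome = exact noisy
        # count vector before clipping.  log P(out|c)/P(out|c') <= eps must
        # hold for every outcome.
        b = 2.0 / epsilon
        a = 1.0 / b
        c, c_prime = np.array([2, 1]), np.array([1, 2])
        worst = 0.0
        for k0, k1 in itertools.product(range(-30, 31), repeat=2):
            out = np.array([k0, k1])
            lp = stats.dlaplace.logpmf(out - c, a).sum()
            lp_prime = stats.dlaplace.logpmf(out - c_prime, a).sum()
            worst = max(worst, abs(lp - lp_prime))
        assert worst <= epsilon + 1e-9


class TestSmoothedHistogram:
    def test_uniform_on_empty_data(self):
        assert smoothed_histogram_probs([0, 0], 1.0, 5).tolist() == [0.5, 0.5]

    def test_hand_computed_probabilities(self):
        p = smoothed_histogram_probs([10, 0], 2.0, 1)  # 2m/eps = 1
        assert p == pytest.approx([11 / 12, 1 / 12])

    def test_smoothing_vanishes_at_large_epsilon(self):
        p = smoothed_histogram_probs([3, 1], 1e9, 1)
        assert p == pytest.approx([0.75, 0.25], abs=1e-6)

    def test_tiny_draw_from_sparse_histogram(self, rng):
        h = _hist([[3, 0], [0, 0]])
        with pytest.warns(UserWarning):
            out = smoothed_histogram_synthesize(h, PrivacyBudget(1.0), 1, rng)
        assert out.sample.n == 1

    @pytest.mark.parametrize("epsilon", [0.5, 1.0, 2.0])
    def test_dp_ratio_exhaustive(self, epsilon):
        # neighboring counts over 2 cells, m = 2 draws: enumerate all 4
        # outcome sequences and bound the log-probability ratio by eps
        m = 2
        c, c_prime = np.array([3, 1]), np.array([2, 2])
        p = smoothed_histogram_probs(c, epsilon, m)
        p_prime = smoothed_histogram_probs(c_prime, epsilon, m)
        worst = 0.0
        for seq in itertools.product(range(2), repeat=m):
            lp = np.log([p[i] for i in seq]).sum()
            lp_prime = np.log([p_prime[i] for i in seq]).sum()
            worst = max(worst, abs(lp - lp_prime))
        assert worst <= epsilon + 1e-9

    def test_low_epsilon_flattens_toward_uniform(self, rng):
        # at eps=0.1, m=500 the synthetic groups are near-uniform over bins:
        # closer to uniform (in total variation) than the original histogram
        s = gaussian_two_group(GaussianSpec(mode="null", n=20000), rng)
        h = build_joint_histogram(s, GAUSSIAN_BINS)
        out = smoothed_histogram_synthesize(h, PrivacyBudget(0.1), 500, rng)
        syn_h = build_joint_histogram(out.sample, GAUSSIAN_BINS)
        uniform = np.full(GAUSSIAN_BINS.n_bins, 1.0 / GAUSSIAN_BINS.n_bins)
        for g in (0, 1):
            orig = h.counts[g] / h.counts[g].sum()
            syn = syn_h.counts[g] / max(syn_h.counts[g].sum(), 1)
            tv_orig = 0.5 * np.abs(orig - uniform).sum()
            tv_syn = 0.5 * np.abs(syn - uniform).sum()
            assert tv_syn < tv_orig

    def test_invalid_arguments(self, rng):
        h = _hist([[1, 0], [0, 0]])
        with pytest.raises(ValueError):
            smoothed_histogram_probs([1, 2], -1.0, 5)
        with pytest.raises(ValueError):
            smoothed_histogram_probs([], 1.0, 5)
        with pytest.raises(ValueError):
            smoothed_histogram_synthesize(h, PrivacyBudget(1.0), 0, rng)


class TestMWEM:
    def test_zero_iterations_rejected(self, rng):
        wl = marginal_workload((2, 2))
        with pytest.raises(ValueError):
            mwem_fit([1, 0, 0, 1], wl, PrivacyBudget(1.0), T=0, rng=rng)

    def test_single_cell_domain_stays_degenerate(self, rng):
        wl = marginal_workload((1,), orders=(1,))
        state = mwem_fit([4], wl, PrivacyBudget(1.0), T=1, rng=rng)
        assert state.weights.tolist() == [1.0]

    def test_no_noise_limit_matches_marginals(self, rng):
        counts = np.array([[10, 0, 5, 5], [2, 8, 6, 4]]).ravel()
        wl = marginal_workload((2, 4))
        state = mwem_fit(counts, wl, PrivacyBudget(1e6), T=10, rng=rng)
        n = counts.sum()
        err = np.abs(wl.answers(n * state.weights) - wl.answers(counts))
        assert err.max() <= 0.01 * n

    def test_weights_stay_normalized_and_nonnegative(self, rng):
        counts = np.array([[7, 1, 0, 2], [0, 3, 9, 1]]).ravel()
        wl = marginal_workload((2, 4))
        state = mwem_fit(counts, wl, PrivacyBudget(1.0), T=5, rng=rng)
        assert (state.weights >= 0).all()
        assert state.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(state.measured_queries) == 5

    def test_sampling_frequencies_match_weights(self, rng):
        state = MWEMState(np.array([0.5, 0.5]), 1, 1.0)
        cells = mwem_sample(state, 100_000, rng)
        freq = (cells == 0).mean()
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(100_000)

    def test_point_mass_weights_give_identical_records(self, rng):
        state = MWEMState(np.array([0.0, 1.0, 0.0, 0.0]), 1, 1.0)
        assert (mwem_sample(state, 50, rng) == 1).all()

    def test_synthesize_matches_original_size_by_default(self, rng):
        s = gaussian_two_group(GaussianSpec(mode="null", n=400), rng)
        h = build_joint_histogram(s, GAUSSIAN_BINS)
        out = mwem_synthesize(h, PrivacyBudget(5.0), rng)
        assert out.sample.n == 400

    def test_workload_queries_have_sensitivity_one(self):
        # within each marginal every cell belongs to exactly one query, so a
        # one-record change moves any single answer by at most one
        wl = marginal_workload((2, 3, 2))
        col_sums_per_marginal = np.asarray(wl.queries.sum(axis=0)).ravel()
        # 3 one-way + 3 two-way marginals cover every cell once each
        assert (col_sums_per_marginal == 6).all()
        assert (wl.queries.data == 1).all()


class TestDeterminism:
    def test_identical_seeds_give_identical_synthetic_data(self):
        s = gaussian_two_group(GaussianSpec(mode="null", n=300), np.random.default_rng(5))
        h = build_joint_histogram(s, GAUSSIAN_BINS)
        for synth in (
            lambda r: perturbed_histogram_synthesize(h, PrivacyBudget(1.0), r),
            lambda r: smoothed_histogram_synthesize(h, PrivacyBudget(1.0), 20, r),
            lambda r: mwem_synthesize(h, PrivacyBudget(1.0), r, T=3),
        ):
            a = synth(np.random.default_rng(11)).sample
            b = synth(np.random.default_rng(11)).sample
            assert np.array_equal(a.labels, b.labels)
            assert np.array_equal(a.values, b.values)
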