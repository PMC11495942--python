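"""Differentially private synthetic-data generators.

Three histogram/marginal-based synthesizers over the (group x bin) domain:

* **Perturbed histogram** — independent discrete-Laplace noise on every
  cell count, negatives clipped to zero, records emitted from the noisy
  counts.  Pure ε-DP.
* **Smoothed histogram** — draws m records i.i.d. from cell probabilities
  proportional to ``c_i + 2m/ε``; the additive smoothing is what buys the
  privacy, so utility degrades as m grows.
* **MWEM** — multiplicative weights / exponential mechanism: an iterative
  approximation of the data distribution that repeatedly selects the
  worst-approximated counting query (exponential mechanism), measures it
  with Laplace noise, and re-weights.

All mechanisms consume a ``numpy.random.Generator`` and are deterministic
given (inputs, generator state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse

from .histograms import JointHistogram, TwoGroupSample, records_from_counts

__all__ = [
    "PrivacyBudget",
    "SyntheticDataset",
    "QueryWorkload",
    "MWEMState",
    "sample_discrete_laplace",
    "perturbed_histogram_synthesize",
    "smoothed_histogram_probs",
    "smoothed_histogram_synthesize",
    "marginal_workload",
    "mwem_fit",
    "mwem_sample",
    "mwem_synthesize",
]


@dataclass(frozen=True)
class PrivacyBudget:
    """An (ε, δ) differential-privacy budget; δ = 0 means pure ε-DP."""

    epsilon: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not (0 <= self.delta < 1):
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")


@dataclass(frozen=True)
class SyntheticDataset:
    """A synthetic two-group sample plus the provenance of its generation."""

    sample: TwoGroupSample
    method: str
    budget: PrivacyBudget
    requested_size: int | str = "match-original"
    seed: int | None = None


def sample_discrete_laplace(b: float, rng: np.random.Generator, size=None):
    """Draw from the discrete Laplace distribution P(k) ∝ exp(−|k|/b).

    Implemented as the difference of two i.i.d. geometric variables with
    success probability 1 − e^(−1/b), which has exactly the two-sided
    geometric pmf.  Returns a Python int when ``size`` is None.
    """
    if not b > 0:
        raise ValueError(f"scale must be positive, got {b}")
    p = -np.expm1(-1.0 / b)  # 1 - e^{-1/b}, accurate for large b
    g1 = rng.geometric(p, size=size)
    g2 = rng.geometric(p, size=size)
    out = g1 - g2
    return int(out) if size is None else out


def perturbed_histogram_synthesize(
    hist: JointHistogram, budget: PrivacyBudget, rng: np.random.Generator
) -> SyntheticDataset:
    """DP perturbed histogram: noise every cell, clip negatives, emit records.

    Adds an independent discrete-Laplace draw at scale 2/ε to each of the
    2 x n_bins counts (L1 sensitivity of the histogram is 2 under
    replace-one adjacency).  The synthetic size is the sum of the clipped
    noisy counts, hence only approximately the original size.
    """
    if budget.delta != 0:
        raise ValueError("perturbed histogram is a pure ε-DP mechanism; delta must be 0")
    noise = sample_discrete_laplace(2.0 / budget.epsilon, rng, size=hist.counts.shape)
    noisy = np.maximum(hist.counts + noise, 0)
    sample = records_from_counts(noisy, hist.bin_spec)
    return SyntheticDataset(sample, "perturbed_hist", budget)


def smoothed_histogram_probs(counts, epsilon: float, m: int) -> np.ndarray:
    """Cell probabilities p_i ∝ c_i + 2m/ε of the smoothed histogram."""
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if m < 1:
        raise ValueError(f"synthetic size m must be >= 1, got {m}")
    counts = np.asarray(counts, dtype=np.float64).ravel()
    if counts.size == 0:
        raise ValueError("cannot smooth an empty domain")
    smoothed = counts + 2.0 * m / epsilon
    return smoothed / smoothed.sum()


def smoothed_histogram_synthesize(
    hist: JointHistogram, budget: PrivacyBudget, m: int, rng: np.random.Generator
) -> SyntheticDataset:
    """Draw m records i.i.d. from the smoothed cell probabilities."""
    if m > hist.n / 10:
        warnings.warn(
            f"smoothed histogram drawn with m={m} > n/10 (n={hist.n}); the method "
            "is intended for synthetic sizes considerably smaller than the original",
            stacklevel=2,
        )
    probs = smoothed_histogram_probs(hist.counts.ravel(), budget.epsilon, m)
    cells = rng.choice(probs.size, size=m, p=probs)
    counts = np.bincount(cells, minlength=probs.size).reshape(2, hist.bin_spec.n_bins)
    sample = records_from_counts(counts, hist.bin_spec)
    return SyntheticDataset(sample, "smoothed_hist", budget, requested_size=m)


# ---------------------------------------------------------------------------
# MWEM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QueryWorkload:
    """Linear counting queries as a sparse 0/1 indicator matrix over cells.

    Each row is one query; the answer on a (possibly fractional) cell-count
    vector v is the dot product row·v.  Indicator queries have sensitivity 1:
    replacing one record changes the answer by at most 1.
    """

    queries: sparse.csr_matrix
    description: str = ""

    def __len__(self) -> int:
        return self.queries.shape[0]

    @property
    def n_cells(self) -> int:
        return self.queries.shape[1]

    def answers(self, cell_vector: np.ndarray) -> np.ndarray:
        return self.queries @ np.asarray(cell_vector, dtype=np.float64)

    def indicator(self, query_index: int) -> np.ndarray:
        return np.asarray(self.queries[query_index].todense()).ravel()


def marginal_workload(shape, orders=(1, 2), description: str | None = None) -> QueryWorkload:
    """All marginal cell-indicator queries of the given orders over a gridded domain.

    For each subset S of axes with \\|S\\| in ``orders`` and each category
    combination of S, the query indicates the domain cells projecting onto
    that combination.  ``orders=(1, 2)`` preserves all one-way and two-way
    marginals.
    """
    shape = tuple(int(s) for s in shape)
    n_cells = int(np.prod(shape))
    cell_multi = np.array(np.unravel_index(np.arange(n_cells), shape))  # (n_axes, n_cells)
    rows, cols = [], []
    row_offset = 0
    for order in orders:
        if order < 1 or order > len(shape):
            raise ValueError(f"marginal order {order} invalid for {len(shape)} axes")
        for axes in combinations(range(len(shape)), order):
            sub_shape = tuple(shape[a] for a in axes)
            # projection index of every cell onto the selected axes
            proj = np.ravel_multi_index(tuple(cell_multi[a] for a in axes), sub_shape)
            rows.append(row_offset + proj)
            cols.append(np.arange(n_cells))
            row_offset += int(np.prod(sub_shape))
    q = sparse.csr_matrix(
        (np.ones(sum(r.size for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(row_offset, n_cells),
    )
    if description is None:
        description = f"all {'/'.join(str(o) for o in orders)}-way marginals of domain {shape}"
    return QueryWorkload(q, description)


@dataclass
class MWEMState:
    """The learned cell distribution and measurement trace of an MWEM run."""

    weights: np.ndarray
    iterations: int
    per_iteration_budget: float
    measured_queries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = w


def mwem_fit(
    counts,
    workload: QueryWorkload,
    budget: PrivacyBudget,
    T: int = 30,
    rng: np.random.Generator | None = None,
    update_sweeps: int = 20,
) -> MWEMState:
    """Run T MWEM iterations against a workload of counting queries.

    Starting from the uniform distribution A over cells, each iteration
    spends ε/(2T) selecting the workload query with the largest absolute
    error on n·A via the exponential mechanism (utility = error,
    sensitivity 1), then ε/(2T) measuring the selected query with Laplace
    noise (scale 2T/ε).  The multiplicative-weights update

        A(x) ← A(x) · exp( q(x) · (m_t − q(n·A)) / (2n) )

    (with renormalization) is then iterated ``update_sweeps`` times over
    the full measurement trace, the standard refinement that makes the
    synthetic distribution actually fit the noisy measurements — including
    their noise, which is what degrades downstream test validity at low ε.
    Both budget halves touch the data once per iteration; the update loop
    is pure post-processing.
    """
    if T < 1:
        raise ValueError(f"number of iterations T must be >= 1, got {T}")
    if update_sweeps < 1:
        raise ValueError(f"update_sweeps must be >= 1, got {update_sweeps}")
    if len(workload) == 0:
        raise ValueError("workload must contain at least one query")
    if rng is None:
        rng = np.random.default_rng()
    counts = np.asarray(counts, dtype=np.float64).ravel()
    if counts.size != workload.n_cells:
        raise ValueError(
            f"counts has {counts.size} cells but workload expects {workload.n_cells}"
        )
    n = counts.sum()
    if n <= 0:
        raise ValueError("data must contain at least one record")

    eps_iter = budget.epsilon / T
    eps_select = eps_iter / 2.0
    eps_measure = eps_iter / 2.0
    true_answers = workload.answers(counts)
    weights = np.full(counts.size, 1.0 / counts.size)
    trace: list[tuple[int, float]] = []
    indicators: dict[int, np.ndarray] = {}

    for _ in range(T):
        syn_answers = workload.answers(n * weights)
        scores = np.abs(true_answers - syn_answers)
        # exponential mechanism, sensitivity-1 utility; rng breaks ties
        logits = eps_select * scores / 2.0
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        qi = int(rng.choice(scores.size, p=probs))
        m_t = float(true_answers[qi] + rng.laplace(scale=1.0 / eps_measure))
        trace.append((qi, m_t))
        if qi not in indicators:
            indicators[qi] = workload.indicator(qi)

        for _ in range(update_sweeps):
            for qj, mj in trace:
                q_x = indicators[qj]
                est = q_x @ weights * n
                weights = weights * np.exp(q_x * (mj - est) / (2.0 * n))
                weights /= weights.sum()

    return MWEMState(weights, T, eps_iter, trace)


def mwem_sample(state: MWEMState, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m cell indices i.i.d. from the learned MWEM weights."""
    if m < 1:
        raise ValueError(f"synthetic size m must be >= 1, got {m}")
    return rng.choice(state.weights.size, size=m, p=state.weights)


def mwem_synthesize(
    hist: JointHistogram,
    budget: PrivacyBudget,
    rng: np.random.Generator,
    T: int = 30,
    m: int | None = None,
    workload: QueryWorkload | None = None,
) -> SyntheticDataset:
    """Fit MWEM on a two-group histogram and sample a synthetic dataset.

    Defaults preserve all one-way and two-way marginals of the
    (group, bin) domain; synthetic size defaults to the original size.
    """
    if workload is None:
        workload = marginal_workload((2, hist.bin_spec.n_bins))
    if m is None:
        m = hist.n
    state = mwem_fit(hist.counts.ravel(), workload, budget, T=T, rng=rng)
    cells = mwem_sample(state, m, rng)
    counts = np.bincount(cells, minlength=2 * hist.bin_spec.n_bins).reshape(
        2, hist.bin_spec.n_bins
    )
    sample = records_from_counts(counts, hist.bin_spec)
    return SyntheticDataset(sample, "mwem", budget, requested_size=m)
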