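"""Experiment harness: Type I / Type II error grids with feasibility conditioning.

One *cell* = (generator, mode, synthesizer, ε, original size, synthetic
size, test).  Per repetition the harness draws fresh original data,
optionally pushes it through a DP synthesizer, runs the test, and records
a rejection at level α (strict inequality p < α).  Under a true null the
rejection proportion estimates the Type I error; under signal, one minus
it estimates the Type II error.  A cell's estimate is flagged as not
reportable when the test's requirements were met in fewer than 50
repetitions.

Repetition seeds are counter-based substreams of the master seed keyed by
a hash of the cell, so every cell is reproducible in any execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dp_mw import DPMWConfig, dp_mw_u_test
from .generators import (
    CopulaSpec,
    GaussianSpec,
    MultivariateDomain,
    copula_simulate,
    default_multivariate_domain,
    gaussian_two_group,
)
from .histograms import GAUSSIAN_BINS, BinSpec, TwoGroupSample, build_joint_histogram
from .stat_tests import run_test
from .synthesizers import (
    PrivacyBudget,
    marginal_workload,
    mwem_fit,
    mwem_sample,
    perturbed_histogram_synthesize,
    sample_discrete_laplace,
    smoothed_histogram_probs,
    smoothed_histogram_synthesize,
)

__all__ = ["ExperimentConfig", "ErrorRateEstimate", "run_cell", "run_grid", "enumerate_cells"]

SYNTHESIZERS = ("none", "dpmw", "perturbed", "smoothed", "mwem")

#: which simulated patient variable each test is applied to
COPULA_TEST_VARIABLE = {"mwu": "pirads", "ttest": "age", "median": "psa", "chi2": "ari5"}

MIN_REPORTABLE_FEASIBLE = 50


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Rejection proportion for one grid cell, conditioned on feasibility."""

    generator: str
    mode: str
    synthesizer: str
    epsilon: float | None
    n_original: int
    n_synthetic: int | str
    test: str
    repetitions: int
    feasible_count: int
    rejections: int
    reported: bool

    @property
    def proportion(self) -> float:
        return self.rejections / self.feasible_count if self.feasible_count else float("nan")

    @property
    def error_rate(self) -> float:
        """Type I error under null mode, Type II error under signal mode."""
        return self.proportion if self.mode == "null" else 1.0 - self.proportion

    def to_row(self) -> dict:
        return {
            "generator": self.generator, "mode": self.mode,
            "synthesizer": self.synthesizer, "epsilon": self.epsilon,
            "n_original": self.n_original, "n_synthetic": self.n_synthetic,
            "test": self.test, "reps": self.repetitions,
            "feasible": self.feasible_count, "rejections": self.rejections,
            "proportion": self.proportion, "reported": self.reported,
        }


@dataclass
class ExperimentConfig:
    """Full factorial grid specification."""

    generator: str = "gaussian"
    modes: tuple = ("null",)
    synthesizers: tuple = ("none",)
    epsilons: tuple = (0.01, 0.1, 1.0, 5.0, 10.0)
    n_original: tuple = (50, 100, 500, 1000, 20000)
    synthetic_sizes: tuple | str = "match-original"
    repetitions: int = 1000
    alpha: float = 0.05
    tests: tuple = ("mwu",)
    master_seed: int = 0
    mwem_T: int = 30
    dpmw_size_fraction: float = 0.65
    dpmw_delta: float = 1e-6
    dpmw_null_reps: int = 2000
    bin_spec: BinSpec = GAUSSIAN_BINS
    copula_spec: CopulaSpec | None = None
    copula_domain: MultivariateDomain | None = None

    def __post_init__(self) -> None:
        if not self.epsilons:
            raise ValueError("epsilon grid must be nonempty")
        if not self.n_original:
            raise ValueError("original-size grid must be nonempty")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for s in self.synthesizers:
            if s not in SYNTHESIZERS:
                raise ValueError(f"unknown synthesizer {s!r}; expected one of {SYNTHESIZERS}")


def _cell_rng(master_seed: int, cell_key: str, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(cell_key.encode()), rep))
    return np.random.default_rng(ss)


def _synthesize_cells(counts, synthesizer, epsilon, m, mwem_T, workload, rng):
    """Generic DP synthesis on a flattened cell-count vector -> cell indices."""
    counts = np.asarray(counts)
    if synthesizer == "perturbed":
        noise = sample_discrete_laplace(2.0 / epsilon, rng, size=counts.shape)
        noisy = np.maximum(counts + noise, 0)
        return np.repeat(np.arange(counts.size), noisy)
    if synthesizer == "smoothed":
        probs = smoothed_histogram_probs(counts, epsilon, m)
        return rng.choice(counts.size, size=m, p=probs)
    state = mwem_fit(counts, workload, PrivacyBudget(epsilon), T=mwem_T, rng=rng)
    return mwem_sample(state, m, rng)


def run_cell(
    *,
    generator: str = "gaussian",
    mode: str = "null",
    synthesizer: str = "none",
    epsilon: float | None = None,
    n_original: int = 1000,
    n_synthetic: int | str = "match-original",
    test: str = "mwu",
    repetitions: int = 1000,
    alpha: float = 0.05,
    master_seed: int = 0,
    mwem_T: int = 30,
    dpmw_size_fraction: float = 0.65,
    dpmw_delta: float = 1e-6,
    dpmw_null_reps: int = 2000,
    bin_spec: BinSpec = GAUSSIAN_BINS,
    copula_spec: CopulaSpec | None = None,
    copula_domain: MultivariateDomain | None = None,
) -> ErrorRateEstimate:
    """Estimate the rejection proportion for one grid cell."""
    if synthesizer not in SYNTHESIZERS:
        raise ValueError(f"unknown synthesizer {synthesizer!r}")
    if synthesizer != "none" and epsilon is None:
        raise ValueError(f"synthesizer {synthesizer!r} requires an epsilon")
    key = f"{generator}|{mode}|{synthesizer}|{epsilon}|{n_original}|{n_synthetic}|{test}"

    workload = None
    if generator == "copula":
        copula_spec = copula_spec or CopulaSpec()
        copula_domain = copula_domain or default_multivariate_domain()
        variable = COPULA_TEST_VARIABLE[test]
        if synthesizer == "mwem":
            workload = marginal_workload(copula_domain.shape)
    elif synthesizer == "mwem":
        workload = marginal_workload((2, bin_spec.n_bins))

    m = n_original if n_synthetic == "match-original" else int(n_synthetic)
    feasible = rejections = 0
    for rep in range(repetitions):
        rng = _cell_rng(master_seed, key, rep)
        try:
            if generator == "gaussian":
                original = gaussian_two_group(GaussianSpec(mode=mode, n=n_original), rng)
                if synthesizer == "none":
                    data = original
                elif synthesizer == "dpmw":
                    result = dp_mw_u_test(
                        original,
                        DPMWConfig(epsilon, dpmw_delta, dpmw_size_fraction, dpmw_null_reps),
                        rng,
                    )
                    data = None
                else:
                    hist = build_joint_histogram(original, bin_spec)
                    budget = PrivacyBudget(epsilon)
                    if synthesizer == "perturbed":
                        data = perturbed_histogram_synthesize(hist, budget, rng).sample
                    elif synthesizer == "smoothed":
                        data = smoothed_histogram_synthesize(hist, budget, m, rng).sample
                    else:
                        state = mwem_fit(hist.counts.ravel(), workload, budget,
                                         T=mwem_T, rng=rng)
                        cells = mwem_sample(state, m, rng)
                        counts = np.bincount(cells, minlength=2 * bin_spec.n_bins)
                        from .histograms import records_from_counts

                        data = records_from_counts(
                            counts.reshape(2, bin_spec.n_bins), bin_spec)
            else:  # copula
                df = copula_simulate(copula_spec, n_original, mode, rng)
                if synthesizer in ("none", "dpmw"):
                    data = TwoGroupSample(df["label"].to_numpy(),
                                          df[variable].to_numpy(dtype=float))
                    if synthesizer == "dpmw":
                        result = dp_mw_u_test(
                            data,
                            DPMWConfig(epsilon, dpmw_delta, dpmw_size_fraction,
                                       dpmw_null_reps),
                            rng,
                        )
                        data = None
                else:
                    counts = copula_domain.counts(df)
                    cells = _synthesize_cells(counts, synthesizer, epsilon, m,
                                              mwem_T, workload, rng)
                    syn = copula_domain.decode(cells)
                    data = TwoGroupSample(syn["label"].to_numpy(),
                                          syn[variable].to_numpy(dtype=float))
            if data is not None:
                result = run_test(data, test)
        except ValueError:
            continue  # repetition infeasible (e.g. empty synthetic sample)
        if result.feasible:
            feasible += 1
            if result.rejects(alpha):
                rejections += 1

    return ErrorRateEstimate(
        generator, mode, synthesizer, epsilon, n_original,
        "n/a" if synthesizer in ("none", "dpmw") else m, test,
        repetitions, feasible, rejections,
        reported=feasible >= MIN_REPORTABLE_FEASIBLE,
    )


def enumerate_cells(config: ExperimentConfig) -> list[dict]:
    """The Cartesian grid of cells a config spans, with the degenerate axes
    (ε for the raw test, synthetic size for raw/DP-MW paths) collapsed."""
    sizes = (
        ["match-original"]
        if config.synthetic_sizes == "match-original"
        else list(config.synthetic_sizes)
    )
    cells = []
    for mode in config.modes:
        for synth in config.synthesizers:
            eps_axis = [None] if synth == "none" else list(config.epsilons)
            size_axis = ["n/a"] if synth in ("none", "dpmw") else sizes
            for eps in eps_axis:
                for n in config.n_original:
                    for m in size_axis:
                        for test in config.tests:
                            cells.append(
                                dict(generator=config.generator, mode=mode,
                                     synthesizer=synth, epsilon=eps, n_original=n,
                                     n_synthetic="match-original" if m == "n/a" else m,
                                     test=test)
                            )
    return cells


def run_grid(config: ExperimentConfig, cell_filter: str | None = None) -> pd.DataFrame:
    """Run every cell of the grid; returns one tidy row per (cell, test).

    ``cell_filter`` keeps only cells whose key contains the substring,
    which is also how an interrupted run is resumed.
    """
    rows = []
    for cell in enumerate_cells(config):
        key = "|".join(str(cell[k]) for k in
                       ("generator", "mode", "synthesizer", "epsilon",
                        "n_original", "n_synthetic", "test"))
        if cell_filter and cell_filter not in key:
            continue
        est = run_cell(
            repetitions=config.repetitions, alpha=config.alpha,
            master_seed=config.master_seed, mwem_T=config.mwem_T,
            dpmw_size_fraction=config.dpmw_size_fraction,
            dpmw_delta=config.dpmw_delta, dpmw_null_reps=config.dpmw_null_reps,
            bin_spec=config.bin_spec, copula_spec=config.copula_spec,
            copula_domain=config.copula_domain, **cell,
        )
        rows.append(est.to_row())
    return pd.DataFrame(rows)
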