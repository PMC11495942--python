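"""Discretization and joint (group x value-bin) histograms.

Every synthesizer in this package privatizes the same object: a 2 x n_bins
contingency table of counts, one row per group.  This module owns the
discretization convention (half-open bins, optional clipping of the tails
into the edge bins), the construction of that table from record-level data,
and the inverse map back to records via bin centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinSpec",
    "TwoGroupSample",
    "JointHistogram",
    "GAUSSIAN_BINS",
    "PSA_BINS",
    "BMI_BINS",
    "discretize",
    "build_joint_histogram",
    "records_from_counts",
    "marginals",
    "read_two_group_csv",
    "write_two_group_csv",
]


@dataclass(frozen=True)
class BinSpec:
    """Equal-width binning of a real interval.

    Bins are half-open ``[left, right)``; the last bin is closed on the
    right when ``overflow_to_last`` is set (values >= ``upper`` clip into
    it), and values below ``lower`` clip into the first bin when
    ``underflow_to_first`` is set.  With clipping disabled, out-of-range
    values are an error.
    """

    n_bins: int
    lower: float
    upper: float
    underflow_to_first: bool = False
    overflow_to_last: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not self.lower < self.upper:
            raise ValueError(
                f"lower must be < upper, got lower={self.lower}, upper={self.upper}"
            )

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        """Arithmetic midpoints of the bin edges."""
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "lower": self.lower,
            "upper": self.upper,
            "clip_low": self.underflow_to_first,
            "clip_high": self.overflow_to_last,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinSpec":
        return cls(
            n_bins=int(d["n_bins"]),
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            underflow_to_first=bool(d.get("clip_low", False)),
            overflow_to_last=bool(d.get("clip_high", False)),
        )


#: 100 unit-width bins labelled 1..100 for the Gaussian two-group data
#: (values near N(50, 2)); both tails clip into the edge bins.
GAUSSIAN_BINS = BinSpec(100, 0.5, 100.5, underflow_to_first=True, overflow_to_last=True)

#: 40 unit-width PSA bins [1, 2), ..., [40, 41); PSA >= 40 lands in the last bin.
PSA_BINS = BinSpec(40, 1.0, 41.0, underflow_to_first=True, overflow_to_last=True)

#: 24 BMI bins: open tail below 18, unit-width 18..40, open tail at >= 40.
BMI_BINS = BinSpec(24, 17.0, 41.0, underflow_to_first=True, overflow_to_last=True)


@dataclass(frozen=True)
class TwoGroupSample:
    """Record-level two-group data: a 0/1 label and a numeric value per record."""

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if labels.shape != values.shape or labels.ndim != 1:
            raise ValueError("labels and values must be 1-D arrays of equal length")
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 1))

    def group(self, label: int) -> np.ndarray:
        return self.values[self.labels == label]


@dataclass(frozen=True)
class JointHistogram:
    """2 x n_bins table of non-negative integer counts."""

    counts: np.ndarray
    bin_spec: BinSpec

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, self.bin_spec.n_bins):
            raise ValueError(
                f"counts must have shape (2, {self.bin_spec.n_bins}), got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def discretize(values, spec: BinSpec) -> np.ndarray:
    """Map values to 0-based bin indices under ``spec``.

    Raises ValueError naming the offending value when it falls outside
    [lower, upper) and the corresponding clip flag is off.
    """
    values = np.asarray(values, dtype=np.float64)
    low = values < spec.lower
    high = values >= spec.upper
    if low.any() and not spec.underflow_to_first:
        bad = values[low][0]
        raise ValueError(f"value {bad} below lower bound {spec.lower} with clipping disabled")
    if high.any() and not spec.overflow_to_last:
        bad = values[high][0]
        raise ValueError(f"value {bad} at or above upper bound {spec.upper} with clipping disabled")
    idx = np.floor((values - spec.lower) / spec.width).astype(np.int64)
    # floating-point guard: a value just under an edge can round up
    np.clip(idx, 0, spec.n_bins - 1, out=idx)
    idx[low] = 0
    idx[high] = spec.n_bins - 1
    return idx


def build_joint_histogram(sample: TwoGroupSample, spec: BinSpec) -> JointHistogram:
    """Cross-tabulate a two-group sample into a 2 x n_bins count table."""
    if sample.n == 0:
        raise ValueError("cannot build a histogram from an empty sample")
    bins = discretize(sample.values, spec)
    counts = np.zeros((2, spec.n_bins), dtype=np.int64)
    np.add.at(counts, (sample.labels, bins), 1)
    return JointHistogram(counts, spec)


def records_from_counts(counts, spec: BinSpec) -> TwoGroupSample:
    """Expand a 2 x n_bins count table into bin-center records.

    Cell (g, b) with count c emits c records with label g and value equal
    to the midpoint of bin b.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64)
    if counts.shape != (2, spec.n_bins):
        raise ValueError(f"counts must have shape (2, {spec.n_bins})")
    centers = spec.centers
    labels = np.repeat(np.repeat([0, 1], spec.n_bins), counts.ravel())
    values = np.repeat(np.tile(centers, 2), counts.ravel())
    return TwoGroupSample(labels, values)


def marginals(hist: JointHistogram, order: int) -> list[np.ndarray]:
    """One-way (group totals, bin totals) or two-way (flattened joint) marginals."""
    if order == 1:
        return [hist.counts.sum(axis=1), hist.counts.sum(axis=0)]
    if order == 2:
        return [hist.counts.ravel().copy()]
    raise ValueError(f"unsupported marginal order {order}; expected 1 or 2")


def read_two_group_csv(path) -> TwoGroupSample:
    """Read a two-column CSV with header columns ``group`` (0/1) and ``value``."""
    df = pd.read_csv(path)
    missing = {"group", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"CSV {path} missing required column(s): {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"CSV {path} contains a header but no records")
    return TwoGroupSample(df["group"].to_numpy(), df["value"].to_numpy())


def write_two_group_csv(sample: TwoGroupSample, path) -> None:
    pd.DataFrame({"group": sample.labels, "value": sample.values}).to_csv(path, index=False)
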