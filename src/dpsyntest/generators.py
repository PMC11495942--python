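"""Simulated stand-ins for the sensitive study inputs.

Two generators with a *known* ground truth, which is what makes Type I and
Type II error measurable:

* ``gaussian_two_group`` — two groups of a single continuous variable.
  Null mode draws both groups from N(50, 2); signal mode separates the
  group means by exactly one population SD (N(51, 1) vs N(50, 1)).
* ``copula_simulate`` — a mixed-type patient-like dataset (age, PSA,
  prostate volume, 5-ARI use, PI-RADS score, risk label) built from a
  Gaussian copula: correlated latent normals pushed through per-variable
  marginal transforms.  Null mode generates a single class and randomly
  relabels exactly half the records, so the groups are exchangeable by
  construction.

The copula's default parameters are synthetic stand-ins chosen to give a
plausible clinical shape (right-skewed PSA and volume, ordinal PI-RADS,
moderate positive latent correlations); they are not fitted to any real
cohort and are all exposed for configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .histograms import BinSpec, PSA_BINS, TwoGroupSample

__all__ = [
    "GaussianSpec",
    "CopulaSpec",
    "MultivariateRecord",
    "MultivariateDomain",
    "gaussian_two_group",
    "copula_simulate",
    "default_multivariate_domain",
    "load_two_group_csv",
    "bmi_from",
]


@dataclass(frozen=True)
class GaussianSpec:
    """Two-group Gaussian design: shared N(mu, sigma) under the null, a
    one-SD mean shift (mu1=51, sigma1=1 vs mu2=50, sigma2=1) under signal."""

    mode: str = "null"
    n: int = 1000
    group_ratio: float = 0.5
    mu: float = 50.0
    sigma: float = 2.0
    mu1: float = 51.0
    sigma1: float = 1.0
    mu2: float = 50.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("null", "signal"):
            raise ValueError(f"mode must be 'null' or 'signal', got {self.mode!r}")
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if not (0 < self.group_ratio < 1):
            raise ValueError(f"group_ratio must be in (0, 1), got {self.group_ratio}")
        if min(self.sigma, self.sigma1, self.sigma2) <= 0:
            raise ValueError("standard deviations must be positive")


def gaussian_two_group(spec: GaussianSpec, rng: np.random.Generator) -> TwoGroupSample:
    """Draw a two-group Gaussian sample; group sizes split round-half-up."""
    n1 = int(np.floor(spec.n * spec.group_ratio + 0.5))
    n2 = spec.n - n1
    if min(n1, n2) < 1:
        raise ValueError("group_ratio leaves one group empty")
    if spec.mode == "null":
        v1 = rng.normal(spec.mu, spec.sigma, n1)
        v2 = rng.normal(spec.mu, spec.sigma, n2)
    else:
        v1 = rng.normal(spec.mu1, spec.sigma1, n1)
        v2 = rng.normal(spec.mu2, spec.sigma2, n2)
    labels = np.concatenate([np.zeros(n1, dtype=np.int64), np.ones(n2, dtype=np.int64)])
    return TwoGroupSample(labels, np.concatenate([v1, v2]))


# ---------------------------------------------------------------------------
# Gaussian copula patient simulator
# ---------------------------------------------------------------------------

_LATENT_VARS = ("age", "psa", "volume", "ari5", "pirads")


def _default_latent_corr() -> np.ndarray:
    # order: age, psa, volume, ari5, pirads
    r = np.eye(5)
    pairs = {
        ("age", "volume"): 0.3,
        ("age", "psa"): 0.2,
        ("psa", "volume"): 0.3,
        ("psa", "pirads"): 0.4,
        ("ari5", "volume"): 0.3,
    }
    for (a, b), v in pairs.items():
        i, j = _LATENT_VARS.index(a), _LATENT_VARS.index(b)
        r[i, j] = r[j, i] = v
    return r


def _default_class_shifts() -> dict:
    # latent-scale mean shifts applied to the high-risk class in signal mode
    return {"psa": 0.8, "pirads": 0.6, "age": 0.3}


@dataclass(frozen=True)
class CopulaSpec:
    """Gaussian-copula simulator parameters.

    Marginals: age ~ Normal(age_mu, age_sigma); psa ~ psa_scale*Beta(a, b);
    volume ~ volume_scale*Beta(a, b); ari5 binary and pirads ordinal 1..5 by
    thresholding their latent normals.  ``latent_corr`` is the correlation
    of the 5 latent coordinates (age, psa, volume, ari5, pirads);
    ``class_shifts`` are latent mean shifts given to the high-risk class in
    signal mode.  All defaults are synthetic stand-ins.
    """

    age_mu: float = 65.0
    age_sigma: float = 7.0
    psa_beta: tuple = (1.5, 8.0)
    psa_scale: float = 120.0
    volume_beta: tuple = (2.0, 6.0)
    volume_scale: float = 200.0
    ari5_prevalence: float = 0.2
    pirads_probs: tuple = (0.15, 0.20, 0.25, 0.25, 0.15)
    latent_corr: np.ndarray = field(default_factory=_default_latent_corr)
    class_shifts: dict = field(default_factory=_default_class_shifts)

    def __post_init__(self) -> None:
        r = np.asarray(self.latent_corr, dtype=np.float64)
        if r.shape != (5, 5) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1):
            raise ValueError("latent_corr must be a symmetric 5x5 matrix with unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("latent_corr must be positive definite")
        if abs(sum(self.pirads_probs) - 1.0) > 1e-9 or min(self.pirads_probs) <= 0:
            raise ValueError("pirads_probs must be positive and sum to 1")
        if not (0 < self.ari5_prevalence < 1):
            raise ValueError("ari5_prevalence must be in (0, 1)")
        object.__setattr__(self, "latent_corr", r)


@dataclass(frozen=True)
class MultivariateRecord:
    """Schema of one simulated patient."""

    age: float
    psa: float
    volume: float
    ari5: int
    pirads: int
    label: int

    def __post_init__(self) -> None:
        if self.pirads not in range(1, 6):
            raise ValueError(f"pirads must be in 1..5, got {self.pirads}")
        if self.psa < 0 or self.volume < 0:
            raise ValueError("psa and volume must be non-negative")
        if self.ari5 not in (0, 1) or self.label not in (0, 1):
            raise ValueError("ari5 and label must be 0/1")


def copula_simulate(
    spec: CopulaSpec, n: int, mode: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate n patients; columns age, psa, volume, ari5, pirads, label.

    Signal mode: equal class counts, the high-risk class gets the latent
    mean shifts.  Null mode: every record drawn from the low-risk
    parameters, then exactly half relabelled high-risk at random.
    """
    if mode not in ("null", "signal"):
        raise ValueError(f"mode must be 'null' or 'signal', got {mode!r}")
    if n < 2 or n % 2:
        raise ValueError(f"need an even n >= 2 for equal classes, got {n}")
    chol = np.linalg.cholesky(spec.latent_corr)
    z = rng.standard_normal((n, 5)) @ chol.T

    half = n // 2
    labels = np.concatenate([np.zeros(half, dtype=np.int64), np.ones(half, dtype=np.int64)])
    if mode == "signal":
        shift = np.zeros(5)
        for var, s in spec.class_shifts.items():
            shift[_LATENT_VARS.index(var)] = s
        z[labels == 1] += shift
    else:
        rng.shuffle(labels)

    u = stats.norm.cdf(z)
    age = spec.age_mu + spec.age_sigma * z[:, 0]
    psa = spec.psa_scale * stats.beta.ppf(u[:, 1], *spec.psa_beta)
    volume = spec.volume_scale * stats.beta.ppf(u[:, 2], *spec.volume_beta)
    ari5 = (u[:, 3] > 1.0 - spec.ari5_prevalence).astype(np.int64)
    cuts = stats.norm.ppf(np.cumsum(spec.pirads_probs)[:-1])
    pirads = 1 + np.searchsorted(cuts, z[:, 4]).astype(np.int64)

    return pd.DataFrame(
        {"age": age, "psa": psa, "volume": volume, "ari5": ari5, "pirads": pirads,
         "label": labels}
    )


# ---------------------------------------------------------------------------
# Multivariate discretization: flattening mixed variables into one cell grid
# ---------------------------------------------------------------------------


class MultivariateDomain:
    """Bijective indexing between mixed-type records and flattened grid cells.

    Continuous columns are discretized by a :class:`BinSpec` and decoded to
    bin centers; categorical columns map their listed categories to
    consecutive codes.  Cell index = mixed-radix (row-major) encoding of
    the per-variable codes, which is what the marginal-based synthesizers
    consume.
    """

    def __init__(self, codecs: dict, max_cells: int = 1_000_000):
        self.codecs = dict(codecs)
        self.columns = list(codecs)
        self.shape = tuple(
            c.n_bins if isinstance(c, BinSpec) else len(c) for c in codecs.values()
        )
        self.n_cells = int(np.prod(self.shape))
        if self.n_cells > max_cells:
            raise ValueError(
                f"domain has {self.n_cells} cells, exceeding the cap of {max_cells}"
            )

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        """Records -> flattened cell indices."""
        from .histograms import discretize

        codes = []
        for col, codec in self.codecs.items():
            if isinstance(codec, BinSpec):
                codes.append(discretize(df[col].to_numpy(), codec))
            else:
                cats = list(codec)
                code = pd.Categorical(df[col], categories=cats).codes.astype(np.int64)
                if (code < 0).any():
                    bad = df[col][code < 0].iloc[0]
                    raise ValueError(f"value {bad!r} in column {col!r} not in categories {cats}")
                codes.append(code)
        return np.ravel_multi_index(tuple(codes), self.shape)

    def decode(self, cells: np.ndarray) -> pd.DataFrame:
        """Flattened cell indices -> records (bin centers / categories)."""
        multi = np.unravel_index(np.asarray(cells, dtype=np.int64), self.shape)
        out = {}
        for (col, codec), code in zip(self.codecs.items(), multi):
            if isinstance(codec, BinSpec):
                out[col] = codec.centers[code]
            else:
                out[col] = np.asarray(list(codec))[code]
        return pd.DataFrame(out)

    def counts(self, df: pd.DataFrame) -> np.ndarray:
        return np.bincount(self.encode(df), minlength=self.n_cells)


def default_multivariate_domain(
    age_bins: int = 20, psa_bins: int = 40, volume_bins: int = 20,
    max_cells: int = 1_000_000,
) -> MultivariateDomain:
    """The default patient-domain grid (age x psa x volume x ari5 x pirads x label)."""
    return MultivariateDomain(
        {
            "age": BinSpec(age_bins, 35.0, 95.0, True, True),
            "psa": BinSpec(psa_bins, PSA_BINS.lower, PSA_BINS.upper, True, True)
            if psa_bins == PSA_BINS.n_bins
            else BinSpec(psa_bins, 0.0, 120.0, True, True),
            "volume": BinSpec(volume_bins, 0.0, 200.0, True, True),
            "ari5": (0, 1),
            "pirads": (1, 2, 3, 4, 5),
            "label": (0, 1),
        },
        max_cells=max_cells,
    )


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def bmi_from(weight_kg, height_cm):
    """Body mass index kg/m^2 from weight in kg and height in cm."""
    weight_kg = np.asarray(weight_kg, dtype=np.float64)
    height_m = np.asarray(height_cm, dtype=np.float64) / 100.0
    return weight_kg / height_m**2


def load_two_group_csv(path, value_column: str = "value", group_column: str = "group") -> TwoGroupSample:
    """Load a two-group sample from CSV, reporting bad rows by line number.

    Rows with an unparseable value or a group outside {0, 1} are dropped
    with a warning naming their line numbers; more than 1% bad rows is a
    hard error.
    """
    df = pd.read_csv(path)
    for col in (value_column, group_column):
        if col not in df.columns:
            raise ValueError(f"CSV {path} missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"CSV {path} contains a header but no records")
    values = pd.to_numeric(df[value_column], errors="coerce")
    groups = pd.to_numeric(df[group_column], errors="coerce")
    bad = values.isna() | ~groups.isin([0, 1])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        frac = bad.mean()
        if frac > 0.01:
            raise ValueError(
                f"{bad.sum()} of {len(df)} rows ({frac:.1%}) are malformed "
                f"(first lines: {lines[:10]}); refusing to load"
            )
        warnings.warn(f"dropping {bad.sum()} malformed row(s) at lines {lines}", stacklevel=2)
    good = ~bad
    if not good.any():
        raise ValueError(f"CSV {path} has no valid records")
    return TwoGroupSample(
        groups[good].to_numpy(dtype=np.int64), values[good].to_numpy(dtype=np.float64)
    )
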