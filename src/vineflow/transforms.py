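"""Margins and maps between data space and pseudo-copula space.

Continuous variables are mapped to (0, 1) through the empirical CDF with the
rank/(n+1) convention; discrete (count) variables go through the randomized
distributional transform G(x, V) = F_(x) + V (F(x) - F_(x)) with
F_(x) = Pr(X < x), which makes them marginally uniform and lets estimators
built for continuous data operate on counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DiscreteMarginTable",
    "ContinuousECDF",
    "fit_empirical_margin",
    "distributional_transform",
    "probability_transform",
    "jitter_counts",
    "infer_discrete",
    "CLAMP_EPS",
]

CLAMP_EPS = 1e-6


class DegenerateMarginError(ValueError):
    """Raised for empty or constant input where no margin can be fitted."""


class UnknownCategoryError(ValueError):
    """Raised when a value falls outside a discrete margin's support."""


def _clamp(u: np.ndarray) -> np.ndarray:
    return np.clip(u, CLAMP_EPS, 1.0 - CLAMP_EPS)


@dataclass
class DiscreteMarginTable:
    """Empirical pmf/CDF table for an integer-valued variable.

    ``cdf_minus`` holds the left limits F_(x) = Pr(X < x) needed by the
    distributional transform.
    """

    support: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False)
    cdf_minus: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1")
        self.cdf = np.cumsum(self.pmf)
        self.cdf[-1] = 1.0
        self.cdf_minus = np.concatenate([[0.0], self.cdf[:-1]])

    @property
    def discrete(self) -> bool:
        return True

    def _index(self, x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.support, x)
        idx_c = np.clip(idx, 0, len(self.support) - 1)
        bad = (idx >= len(self.support)) | (self.support[idx_c] != x)
        if np.any(bad):
            raise UnknownCategoryError(
                f"values outside margin support: {np.unique(np.asarray(x)[bad])}"
            )
        return idx_c

    def log_pmf(self, x) -> np.ndarray:
        return np.log(self.pmf[self._index(np.asarray(x))])

    def quantile(self, q) -> np.ndarray:
        """Generalized inverse: smallest support value with CDF >= q."""
        idx = np.searchsorted(self.cdf, np.asarray(q, dtype=float), side="left")
        return self.support[np.clip(idx, 0, len(self.support) - 1)]


@dataclass
class ContinuousECDF:
    """Step empirical CDF with rank/(n+1) rescaling (values stay interior)."""

    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        self.sorted_values = np.sort(np.asarray(self.sorted_values, dtype=float))

    @property
    def discrete(self) -> bool:
        return False

    def evaluate(self, x) -> np.ndarray:
        n = len(self.sorted_values)
        r = np.searchsorted(self.sorted_values, np.asarray(x, dtype=float), side="right")
        return _clamp(r / (n + 1.0))

    def quantile(self, q) -> np.ndarray:
        """Empirical quantile, linear between the rank/(n+1) plotting positions."""
        n = len(self.sorted_values)
        pos = np.arange(1, n + 1) / (n + 1.0)
        return np.interp(np.asarray(q, dtype=float), pos, self.sorted_values)


def infer_discrete(x: np.ndarray) -> bool:
    """Auto-flag a column discrete: all integers and few distinct values.

    The cut-off is sqrt(n) distinct values; callers can always override.
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        return False
    if not np.all(x == np.floor(x)):
        return False
    return len(np.unique(x)) <= np.sqrt(len(x))


def fit_empirical_margin(x, discrete: bool):
    """Fit an empirical margin: a pmf table (discrete) or a step ECDF."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateMarginError("need a 1-D sample of length >= 2")
    if np.all(x == x[0]):
        raise DegenerateMarginError("constant input has a degenerate margin")
    if discrete:
        if not np.all(x == np.floor(x)):
            raise ValueError("discrete margin requires integer input")
        support, counts = np.unique(x.astype(np.int64), return_counts=True)
        return DiscreteMarginTable(support=support, pmf=counts / counts.sum())
    return ContinuousECDF(sorted_values=x)


def distributional_transform(x, margin: DiscreteMarginTable, seed=None) -> np.ndarray:
    """Randomized PIT for counts: G(x, V) = F_(x) + V (F(x) - F_(x)), V ~ U(0,1)."""
    x = np.asarray(x)
    idx = margin._index(x)
    rng = np.random.default_rng(seed)
    v = rng.uniform(size=x.shape)
    u = margin.cdf_minus[idx] + v * (margin.cdf[idx] - margin.cdf_minus[idx])
    return _clamp(u)


def probability_transform(x, margin, seed=None) -> np.ndarray:
    """Map samples to (0, 1): ECDF for continuous margins, distributional
    transform for discrete ones."""
    if getattr(margin, "discrete", False):
        return distributional_transform(x, margin, seed=seed)
    return margin.evaluate(x)


def jitter_counts(x, seed=None) -> np.ndarray:
    """Make counts pseudo-continuous by adding U[0,1) jitter; floors are kept."""
    x = np.asarray(x)
    if not np.all(x == np.floor(x)):
        raise ValueError("jitter_counts expects integer input")
    rng = np.random.default_rng(seed)
    return x + rng.uniform(0.0, 1.0, size=x.shape)


def uniformity_ks(u: np.ndarray) -> float:
    """KS statistic of a sample against U(0,1) (diagnostic helper)."""
    return stats.kstest(u, "uniform").statistic
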