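"""Nonparametric group statistics used throughout the analyses.

Group differences are tested with the Mann-Whitney U test (exact by
enumeration for small tie-free samples, normal approximation with tie and
continuity correction otherwise), the Kruskal-Wallis one-way ANOVA on
ranks, or the Pearson chi-square test on contingency tables; Bonferroni
correction is applied over explicitly declared comparison families. Group
summaries are reported as median and interquartile range (Q1-Q3) with
linear (type-7) interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError

EXACT_MAX_N = 8  # exact U-test enumeration up to this per-group size (no ties)


@dataclass
class GroupComparison:
    """Result of one group comparison."""

    statistic: float
    p_value: float
    p_adjusted: float
    n_per_group: tuple[int, ...]
    method: str
    summary: list[tuple[float, float, float]] = field(default_factory=list)


def summarize_median_iqr(values) -> tuple[float, float, float]:
    """Median and (Q1, Q3) by linear interpolation (type-7 convention)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("cannot summarize an empty sample")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return np.unique(combined).size < combined.size


def mann_whitney_u(x, y, mode: str = "auto", family_size: int = 1
                   ) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples.

    ``mode='auto'`` uses the exact null distribution (full enumeration) when
    both samples have at most 8 observations and no ties are present,
    otherwise the normal approximation with tie correction and continuity
    correction. The reported U is the midrank-sum statistic of ``x``;
    swapping the samples maps U to n*m - U and leaves p unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    ties = _has_ties(x, y)
    if mode == "auto":
        use_exact = (max(x.size, y.size) <= EXACT_MAX_N) and not ties
    else:
        use_exact = mode == "exact"
        if use_exact and ties:
            warnings.warn("exact U-test requested with ties present; "
                          "p-value ignores the ties", RuntimeWarning,
                          stacklevel=2)
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(res.pvalue)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=p,
        p_adjusted=min(1.0, family_size * p),
        n_per_group=(x.size, y.size),
        method=f"mann-whitney-u/{method}",
        summary=[summarize_median_iqr(x), summarize_median_iqr(y)],
    )


def kruskal_wallis(groups, family_size: int = 1) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups.

    When every value across all groups ties, H is 0 by convention and the
    p-value is undefined (NaN) with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidParameterError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise InvalidParameterError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across groups; H = 0, p undefined",
                      RuntimeWarning, stacklevel=2)
        stat, p = 0.0, float("nan")
    else:
        stat, p = sps.kruskal(*arrays)
        stat, p = float(stat), float(p)
    return GroupComparison(
        statistic=stat,
        p_value=p,
        p_adjusted=min(1.0, family_size * p) if np.isfinite(p) else float("nan"),
        n_per_group=tuple(a.size for a in arrays),
        method="kruskal-wallis",
        summary=[summarize_median_iqr(a) for a in arrays],
    )


def chi_square(table, family_size: int = 1) -> GroupComparison:
    """Pearson chi-square test of independence on a contingency table
    (no continuity correction; df = (r-1)(c-1))."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise InvalidParameterError("need an r x c contingency table, r,c >= 2")
    if np.any(tab < 0):
        raise InvalidParameterError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise InvalidParameterError("all marginal sums must be positive")
    res = sps.chi2_contingency(tab, correction=False)
    p = float(res.pvalue)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=p,
        p_adjusted=min(1.0, family_size * p),
        n_per_group=tuple(int(s) for s in tab.sum(axis=1)),
        method="chi-square",
    )


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-adjust p-values: min(1, m * p), order preserved.

    ``family_size`` defaults to the number of p-values; it is declared
    explicitly when the planned family is larger than the list supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must be in [0, 1]")
    m = len(p) if family_size is None else family_size
    if m < 1:
        raise InvalidParameterError("family_size must be >= 1")
    return np.minimum(1.0, m * p)
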