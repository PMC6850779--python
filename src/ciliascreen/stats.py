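"""Nonparametric reporting statistics.

Two-group comparisons use the Mann-Whitney U test with the exact null
distribution whenever the samples are small and tie-free (the exact
two-sided p is twice the smaller tail probability, capped at 1, which is
what yields the familiar small-sample grid: 2/70 = 0.0286 for complete
separation of two groups of four, 34/70 = 0.4857 for U = 5, 2/12870 ≈
0.0002 for two groups of eight).  Three or more groups use
Kruskal-Wallis with the chi-square approximation.  Outlier removal is a
univariate adaptation of the ROUT idea: a robust fit (here a constant,
the median), a robust scale from the 68.27th percentile of absolute
residuals, and FDR-controlled removal of extreme points at level Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "FlowPopulation",
    "TestResult",
    "mann_whitney_exact",
    "kruskal_wallis",
    "rout_outliers",
    "median_fold_change",
    "violin_summary",
    "delta_ct",
    "per_dna_normalize",
]

EXACT_MAX_TOTAL_N = 20


@dataclass
class FlowPopulation:
    """Per-cell fluorescence values (a.u.) with a condition label."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("population must be nonempty")

    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str  # "exact" or "approximation"
    n: tuple[int, ...]


def _as_array(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", x), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("samples must be nonempty")
    return arr


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact when feasible.

    The exact null (full enumeration over rank assignments) is used when
    n_x + n_y <= 20 and the pooled data are tie-free; otherwise the
    normal approximation with tie correction and continuity correction
    is used and flagged in ``method``.
    """
    x, y = _as_array(x), _as_array(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= EXACT_MAX_TOTAL_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approximation",
        n=(len(x), len(y)),
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H across >= 3 groups, chi-square p (k-1 df)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)):
        groups = tuple(groups[0])
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 groups")
    arrays = [_as_array(g) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy rejects the degenerate case
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(h),
        p_two_sided=float(p),
        method="approximation",
        n=tuple(len(a) for a in arrays),
    )


def rout_outliers(values, q: float = 0.10):
    """Robust outlier removal at FDR level ``q`` (kept, removed).

    Residuals are taken from the sample median; the robust scale is the
    68.27th percentile of the absolute residuals (the robust SD
    analogue).  Each point gets a t-like statistic |residual| / scale
    with a two-sided p at n-1 degrees of freedom, and points are removed
    by a Benjamini-Hochberg scan over those p-values at level ``q``,
    which tests from the most extreme point inward.  ``q = 0`` removes
    nothing.  Deterministic.
    """
    values = _as_array(values)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values")
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    keep_all = values.copy(), np.empty(0, dtype=values.dtype)
    if q == 0:
        return keep_all
    resid = np.abs(values - np.median(values))
    scale = np.percentile(resid, 68.27)
    if scale == 0:
        # >68% of points identical: any deviating point is infinitely extreme
        p = np.where(resid > 0, 0.0, 1.0)
    else:
        p = 2.0 * sps.t.sf(resid / scale, df=n - 1)
    order = np.argsort(p, kind="stable")
    thresholds = q * np.arange(1, n + 1) / n
    below = p[order] <= thresholds
    if not below.any():
        return keep_all
    k = int(np.flatnonzero(below).max())
    cut = resid[order[k]]
    removed_mask = resid >= cut
    return values[~removed_mask], values[removed_mask]


def median_fold_change(treated, untreated) -> float:
    """median(treated) / median(untreated)."""
    treated, untreated = _as_array(treated), _as_array(untreated)
    denom = float(np.median(untreated))
    if denom <= 0:
        raise ValueError("untreated median must be positive")
    return float(np.median(treated)) / denom


def violin_summary(values) -> dict[str, float]:
    """Mean and interquartile range (linear-interpolated percentiles)."""
    values = _as_array(values)
    q25, q75 = np.percentile(values, [25, 75])
    return {"mean": float(values.mean()), "q25": float(q25), "q75": float(q75)}


def delta_ct(ct_target: float, ct_reference: float) -> tuple[float, float]:
    """qPCR delta-Ct and relative expression 2^(-dCt)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    dct = ct_target - ct_reference
    return dct, float(2.0 ** (-dct))


def per_dna_normalize(measurement: float, dna: float) -> float:
    """Divide a bulk measurement by the sample's DNA content."""
    if dna <= 0:
        raise ValueError("DNA measurement must be positive")
    return measurement / dna
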