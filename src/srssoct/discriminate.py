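"""Group statistics and the combined two-feature discriminant.

Tumor/healthy comparisons use Student's two-sample t test (equal-variance
pooling, two-sided; Welch available behind a flag).  A one-dimensional
decision rule on a decay coefficient uses the midpoint of the two group
means as threshold.  For the combined two-feature analysis (OCT decay rate
vs nonlinear-phase AUC ratio) the most discriminative direction is
Fisher's linear discriminant, w ∝ Σ_pooled^-1 (μ1 - μ2); per-region
coordinates along that direction are min-max rescaled to [0, 1] and can be
tested like any scalar feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "DiscriminantResult",
    "BoxplotSummary",
    "two_sided_t_test",
    "discriminant_threshold",
    "fisher_direction",
    "project_rescale",
    "boxplot_summary",
]


@dataclass
class GroupComparison:
    group_means: tuple
    t_statistic: float
    p_value: float
    n_per_group: tuple
    test: str = "student"


@dataclass
class DiscriminantResult:
    direction: np.ndarray
    projected: np.ndarray
    threshold: float | None = None


@dataclass
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def two_sided_t_test(x, y, welch: bool = False) -> GroupComparison:
    """Two-sample two-sided t test; Student (pooled variance) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance: degenerate groups")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return GroupComparison(
        group_means=(float(np.mean(x)), float(np.mean(y))),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(x.size, y.size),
        test="welch" if welch else "student",
    )


def discriminant_threshold(tumor_values, healthy_values) -> float:
    """Midpoint of the two group means — the 1D decision threshold."""
    t = np.asarray(tumor_values, dtype=float)
    h = np.asarray(healthy_values, dtype=float)
    if t.size == 0 or h.size == 0:
        raise ValueError("both groups must be non-empty")
    return float((np.mean(t) + np.mean(h)) / 2.0)


def fisher_direction(points_a, points_b, regularization: float = 1e-9) -> np.ndarray:
    """Fisher's linear discriminant direction between two point clouds
    (n x d), unit-normalized.  The pooled covariance is Tikhonov-regularized
    so near-singular clouds still yield a direction."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 points per group")
    na, nb = a.shape[0], b.shape[0]
    cov = ((na - 1) * np.cov(a, rowvar=False) + (nb - 1) * np.cov(b, rowvar=False)) / (
        na + nb - 2
    )
    cov = np.atleast_2d(cov)
    scale = np.trace(cov) / cov.shape[0]
    cov = cov + regularization * max(scale, 1.0) * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, np.mean(a, axis=0) - np.mean(b, axis=0))
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("identical group means: no discriminant direction")
    return w / norm


def project_rescale(points, direction) -> np.ndarray:
    """Scalar coordinates of points along a direction, min-max rescaled to
    [0, 1] (the minimum-projection point is the reference at 0)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    proj = pts @ np.asarray(direction, dtype=float)
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        raise ValueError("all projections identical: cannot rescale")
    return (proj - lo) / (hi - lo)


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles (linear-interpolation rule), 1.5*IQR whiskers at the most
    extreme non-outlier points, and the outliers beyond them."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = (v >= lo_lim) & (v <= hi_lim)
    return BoxplotSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=float(v[inside].min()),
        whisker_hi=float(v[inside].max()),
        outliers=np.sort(v[~inside]),
    )
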