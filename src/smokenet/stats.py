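"""Statistical primitives shared by every pipeline stage.

These are deliberately thin, well-specified wrappers: Benjamini-Hochberg
step-up adjustment (including the top-slice variant needed when only the
k smallest of m raw p-values are in hand), the classical unpaired t-test,
the hypergeometric upper tail used for over-representation, and Pearson
correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "bh_adjust",
    "unpaired_t_test",
    "hypergeom_tail",
    "pearson_correlation",
]


def bh_adjust(values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    values
        Raw p-values, each in [0, 1]. Need not be sorted; the returned
        array is aligned to the input order.
    m_total
        Total number of tests the adjustment is over. Defaults to
        ``len(values)``. May exceed ``len(values)`` when only a top slice
        (the ``len(values)`` smallest of ``m_total`` raw p-values) is
        supplied; the caller is responsible for that slice property.

    Returns
    -------
    numpy.ndarray
        Adjusted p-values ``min_{j: p_j >= p_i} p_j * m_total / rank(p_j)``
        capped at 1, in input order.

    Notes
    -----
    With a top slice the step-up minimum runs over the supplied values
    only. Because adjusted values reordered by ascending raw p are
    non-decreasing, adjusting the k smallest of m p-values with
    ``m_total=m`` gives exactly the first k entries of the full
    adjustment.
    """
    p = np.asarray(values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust requires a non-empty 1-d vector of p-values")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("raw p-values must lie in [0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total ({m}) must be >= number of supplied p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def unpaired_t_test(x, y, equal_variance: bool = True) -> tuple[float, float]:
    """Two-sample t-test for a difference in means.

    Student's pooled-variance test by default (the classical "unpaired
    t-test"); Welch's unequal-variance test when ``equal_variance`` is
    False. Returns ``(t, p)`` with a two-sided p and the sign of ``t``
    following ``mean(x) - mean(y)``.

    When both groups have zero variance and equal means the statistic is
    undefined; by convention this returns ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std() == 0.0 and y.std() == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    t, p = _sps.ttest_ind(x, y, equal_var=equal_variance)
    return float(t), float(p)


def hypergeom_tail(overlap: int, category_size: int, selected_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    ``X`` counts category members in a draw of ``selected_size`` from a
    universe of ``universe_size`` containing ``category_size`` category
    members. This is the one-sided over-representation p-value.
    """
    for name, v in (
        ("overlap", overlap),
        ("category_size", category_size),
        ("selected_size", selected_size),
        ("universe_size", universe_size),
    ):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if category_size > universe_size or selected_size > universe_size:
        raise ValueError("category and selection must fit inside the universe")
    if overlap > min(category_size, selected_size):
        raise ValueError(
            f"overlap ({overlap}) exceeds min(category_size, selected_size) "
            f"({min(category_size, selected_size)})"
        )
    if overlap == 0:
        return 1.0
    return float(_sps.hypergeom.sf(overlap - 1, universe_size, category_size, selected_size))


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(_sps.pearsonr(x, y).statistic)
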