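"""Shared statistical primitives.

All group comparisons in the package go through :func:`students_t_test` so the
zero-variance conventions are applied uniformly: two constant equal groups are
maximally compatible (p = 1), two constant unequal groups are significant at
the machine limit and flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p: float
    degenerate: bool = False


def students_t_test(a, b, *, welch: bool = False) -> TTestResult:
    """Two-sample two-sided t-test (pooled variance by default).

    Parameters
    ----------
    a, b : array-like
        Replicate values, at least 2 per group.
    welch : bool
        Use Welch's unequal-variance test instead of the pooled-variance
        Student's test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires at least 2 replicates per group")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * np.inf, float(np.finfo(float).tiny), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), degenerate=False)


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))
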