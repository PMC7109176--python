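"""Cohort-level statistical comparisons with multiplicity control.

Wraps the classical tests the evaluation uses — paired t, Welch two-sample t
and Pearson correlation — in a uniform :class:`StatReport` record, and applies
Benjamini–Hochberg step-up false-discovery-rate adjustment across whatever
family of reports one invocation emits.  Degenerate inputs (zero-variance
differences, constant samples) produce flagged reports with NaN statistics
rather than exceptions, so that a cohort run never dies on an edge case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatReport",
    "paired_t",
    "two_sample_t",
    "pearson",
    "bh_adjust",
    "adjust_reports",
]


@dataclass(frozen=True)
class StatReport:
    """One hypothesis test: name, statistic, raw and BH-adjusted p, sizes."""

    test: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: float = float("nan")
    groups: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("inputs must be finite")
    return a


def paired_t(x, y, name: str = "paired_t") -> StatReport:
    """Two-sided paired t test (one-sample t on the differences, n-1 df).

    All-equal pairs (zero-variance differences) are degenerate: the t
    statistic is undefined, so the report is flagged with NaN statistic/p.
    """
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return StatReport(name, float("nan"), float("nan"), n, flags=("degenerate",))
    res = sps.ttest_rel(x, y)
    return StatReport(name, float(res.statistic), float(res.pvalue), n)


def two_sample_t(x, y, name: str = "two_sample_t") -> StatReport:
    """Two-sided Welch (unequal-variance) two-sample t test."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("two-sample t requires n >= 2 per group")
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        if np.isclose(x.mean(), y.mean()):
            # identical constant groups: no evidence of difference
            return StatReport(name, 0.0, 1.0, len(x) + len(y), flags=("degenerate",))
        return StatReport(
            name, float("nan"), float("nan"), len(x) + len(y), flags=("degenerate",)
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatReport(name, float(res.statistic), float(res.pvalue), len(x) + len(y))


def pearson(x, y, name: str = "pearson") -> StatReport:
    """Pearson correlation with a two-sided p via the t transform (n-2 df)."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise ValueError("correlation requires equal-length samples")
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    if np.allclose(x.std(ddof=1), 0.0) or np.allclose(y.std(ddof=1), 0.0):
        return StatReport(
            name, float("nan"), float("nan"), len(x), flags=("degenerate",)
        )
    res = sps.pearsonr(x, y)
    return StatReport(name, float(res.statistic), float(res.pvalue), len(x))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_i = min over j with p_j >= p_i of (p_j * m / rank_j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_reports(reports: list[StatReport]) -> list[StatReport]:
    """Fill ``p_adjusted`` across a family of reports by BH, skipping degenerates."""
    idx = [i for i, r in enumerate(reports) if np.isfinite(r.p_value)]
    if not idx:
        return list(reports)
    adj = bh_adjust([reports[i].p_value for i in idx])
    out = list(reports)
    for i, a in zip(idx, adj):
        out[i] = replace(out[i], p_adjusted=float(a))
    return out
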