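"""Shared statistical primitives: BH step-up and row-wise Welch tests."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    q(i) = min over k >= rank(i) of p(k) * m / k, capped at 1.  Raises on
    p-values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values for genes x samples arrays.

    Degenerate rows where both groups have zero variance get p = 1 when the
    group means are equal and p = 0 when they differ, so constant inputs
    behave deterministically.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's catastrophic-cancellation warning; the
        # degenerate convention below overrides those p-values anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        equal_means = a.mean(axis=1) == b.mean(axis=1)
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)
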