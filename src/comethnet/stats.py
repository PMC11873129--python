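"""Shared statistical primitives.

Correlation tests used throughout the pipeline: Spearman on midranks with an
exact permutation p-value at small n, Pearson with the usual t-based p-value,
Wilcoxon rank-sum with exact small-sample handling, and Benjamini-Hochberg
correction. The Spearman estimator is, by construction, Pearson applied to
midranks, so it handles the binary traits (heavily tied) correctly.
"""

from __future__ import annotations

import itertools
import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_test",
    "spearman_test",
    "rank_sum_test",
    "bh_adjust",
    "bonferroni_threshold",
    "format_p_threshold",
]

#: largest n for which the Spearman permutation null is enumerated exactly
EXACT_SPEARMAN_N = 9


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        return float("nan")
    return float(x @ y) / denom


def _t_pvalue(r: float, n: int) -> float:
    if n < 3 or not math.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * sps.t.sf(abs(t), n - 2)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = _pearson_r(x, y)
    return r, _t_pvalue(r, x.size)


def spearman_test(x, y, exact_max_n: int = EXACT_SPEARMAN_N) -> tuple[float, float]:
    """Spearman correlation (Pearson on midranks) with two-sided p-value.

    For n <= ``exact_max_n`` the p-value is computed by enumerating all n!
    permutations of one rank vector; otherwise the t-approximation on the
    observed coefficient is used. Midranks make the estimator well defined
    for binary and otherwise tied data.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _pearson_r(rx, ry)
    if not math.isfinite(r):
        return float("nan"), float("nan")
    if n <= exact_max_n:
        # exact two-sided permutation p: |r_perm| >= |r_obs|
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        perms = np.array(list(itertools.permutations(range(n))))
        stat = (ryc[perms] @ rxc) / denom
        obs = abs(float(rxc @ ryc) / denom)
        p = float(np.mean(np.abs(stat) >= obs - 1e-12))
        return r, p
    return r, _t_pvalue(r, n)


def rank_sum_test(a, b, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= ``exact_max_n``
    observations and no ties span the groups; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaN-aware)."""
    p = np.asarray(pvalues, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_p_threshold(threshold: float) -> str:
    """Render a significance threshold the way it is quoted in reports.

    Uses the uncertainty-reporting convention: two significant figures when
    the leading significant digit is 1 or 2 (where one digit would carry a
    large relative rounding error), one significant figure otherwise, with
    half-up rounding. E.g. 0.05/27 -> '0.0019', 0.05/18 -> '0.0028',
    0.05/8 -> '0.006'.
    """
    if not (threshold > 0):
        raise ValueError("threshold must be positive")
    d = Decimal(repr(threshold))
    exp = d.adjusted()  # floor(log10(|d|))
    lead = int(d.scaleb(-exp).to_integral_value(rounding="ROUND_FLOOR"))
    digits = 2 if lead <= 2 else 1
    quantum = Decimal(1).scaleb(exp - digits + 1)
    rounded = d.quantize(quantum, rounding=ROUND_HALF_UP)
    return format(rounded.normalize(), "f")
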