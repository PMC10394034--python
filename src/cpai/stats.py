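"""Statistical primitives used throughout the pipeline.

Thin, contract-checked wrappers around scipy/statsmodels for the named
tests (Fisher's exact 2x2, Benjamini-Hochberg, two-sided K-S, Wilcoxon
rank-sum, OLS with R^2), plus equal-count binning with deterministic tie
and remainder rules.  All operations are pure and seed-free.
"""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    Two-sidedness is by summation of hypergeometric probabilities no
    larger than the observed table's (the convention of mainstream
    implementations, with a (1 + 1e-7) relative tolerance on "no larger").
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("contingency counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided Kolmogorov-Smirnov test; D = sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("K-S test needs non-empty samples")
    res = scipy.stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples are small (min n <= ``exact_max_n``)
    and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def ols_r2(y, X) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on X with an intercept; returns
    (coefficients incl. intercept first, R^2)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return beta, float(np.clip(r2, 0.0, 1.0))


def equal_count_bins(values, k: int) -> np.ndarray:
    """Assign each item to one of ``k`` equal-count bins by ascending value.

    Bin sizes differ by at most one; when n is not divisible by k the
    remainder items go to the lowest-index bins.  Ties are broken by
    stable input order, so the assignment is deterministic.
    """
    values = np.asarray(values)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(k), sizes)
    return bins
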