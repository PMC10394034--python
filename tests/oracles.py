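"""Independent brute-force oracles used by the test suite.

These are deliberately naive (enumeration / permutation) implementations,
kept separate from the package so that they cannot share code paths with
the functions they check.
"""

from __future__ import annotations

import math

import numpy as np


def hypergeom_pmf_vector(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact hypergeometric pmf over the support of ``a`` for fixed
    margins (row sums r1, r2; first column sum c1)."""
    n = r1 + r2
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    denom = math.comb(n, c1)
    pmf = np.array(
        [math.comb(r1, a) * math.comb(r2, c1 - a) / denom for a in support], dtype=float
    )
    return support, pmf


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities no
    larger than the observed table's (relative gate 1 + 1e-7)."""
    support, pmf = hypergeom_pmf_vector(a + b, c + d, a + c)
    p_obs = pmf[np.searchsorted(support, a)]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def bh_step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def ranksum_permutation_oracle(x, y, n_perm: int = 20000, seed: int = 0) -> float:
    """Two-sided rank-sum p by Monte-Carlo permutation of the pooled
    sample, using the rank-sum statistic with midranks for ties."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def stat(perm):
        ranks = np.empty(len(pooled))
        order = np.argsort(perm, kind="stable")
        sorted_vals = perm[order]
        # midranks
        i = 0
        r = np.empty(len(pooled))
        while i < len(pooled):
            j = i
            while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            r[i : j + 1] = (i + j) / 2 + 1
            i = j + 1
        ranks[order] = r
        return ranks[:nx].sum()

    observed = stat(pooled)
    mu = nx * (len(pooled) + 1) / 2
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat(perm) - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / n_perm


def ecdf_ks_oracle(x, y) -> float:
    """sup |ECDF_x - ECDF_y| by direct evaluation at all pooled points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pts = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, pts, side="right") / len(x)
    fy = np.searchsorted(y, pts, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))
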