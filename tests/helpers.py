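"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own code paths:
residualization through explicit normal equations, correlations through
pairwise scipy.stats.pearsonr, BH through the from-definition step-up,
rank tests through exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import pearsonr


def residualize_oracle(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least squares through explicit normal equations."""
    n = values.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([np.ones(n), covariates])
    beta = np.linalg.solve(X.T @ X, X.T @ values)
    return values - X @ beta


def pairwise_corr_oracle(resid: np.ndarray) -> np.ndarray:
    """Correlation matrix via pairwise scipy pearsonr calls."""
    m = resid.shape[1]
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r = pearsonr(resid[:, i], resid[:, j]).statistic
            out[i, j] = out[j, i] = r
    return out


def brute_force_deviation(
    ref_values: np.ndarray,
    ref_covariates: np.ndarray | None,
    subject_values: np.ndarray,
    subject_covariates: np.ndarray | None,
) -> np.ndarray:
    """Two independent network builds plus the z formula, from scratch."""
    pcc_n = pairwise_corr_oracle(residualize_oracle(ref_values, ref_covariates))
    stacked = np.vstack([ref_values, subject_values])
    if ref_covariates is None:
        stacked_cov = None
    else:
        stacked_cov = np.vstack(
            [np.atleast_2d(ref_covariates), np.atleast_2d(subject_covariates)]
        )
    pcc_n1 = pairwise_corr_oracle(residualize_oracle(stacked, stacked_cov))
    n = ref_values.shape[0]
    z = (pcc_n1 - pcc_n) * (n - 1) / (1.0 - pcc_n**2)
    np.fill_diagonal(z, 0.0)
    return z


def bh_adjust_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg from the definition: adj_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def ranksum_exact_oracle(a, b, alternative="two-sided") -> float:
    """Exact Mann-Whitney p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size
    idx = range(pooled.size)

    def u_stat(ai):
        av = pooled[list(ai)]
        bv = pooled[[i for i in idx if i not in ai]]
        return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

    observed = u_stat(tuple(range(na)))
    us = [u_stat(c) for c in itertools.combinations(idx, na)]
    us = np.array(us)
    p_le = np.mean(us <= observed)
    p_ge = np.mean(us >= observed)
    if alternative == "two-sided":
        return float(min(1.0, 2 * min(p_le, p_ge)))
    if alternative == "less":
        return float(p_le)
    return float(p_ge)


def signed_rank_less_oracle(before, after) -> float:
    """Exact one-sided (after < before) signed-rank p by enumerating all
    2^n sign patterns of the absolute differences (zeros dropped,
    mid-ranks for ties)."""
    from scipy.stats import rankdata

    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_pos_obs = ranks[d > 0].sum()
    count = 0
    total = 2**n
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if w <= w_pos_obs:
            count += 1
    return count / total


def normal_two_tailed_oracle(z: float) -> float:
    """2 * upper-tail standard normal probability via erfc."""
    return math.erfc(abs(z) / math.sqrt(2.0))
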