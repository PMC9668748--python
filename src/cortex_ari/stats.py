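"""Rank-test primitives shared by every attenuation statistic.

The paired Wilcoxon signed-rank test is the unit of work of the whole
pipeline: every permutation and every bootstrap draw re-tests all genes on a
resampled subject set, so the implementation here is vectorised across genes
(rows) and chooses, per row, between an exact null distribution and a normal
approximation.

Null-distribution policy
------------------------
* zero paired differences are dropped before ranking (classical Wilcoxon);
  a row with no nonzero differences gets p = 1;
* no ties among nonzero |d| and at most ``EXACT_MAX`` (25) nonzero pairs:
  exact distribution of W+ computed once per n by dynamic programming;
* ties present and at most ``ENUM_MAX`` (14) nonzero pairs: exact
  enumeration of all 2^n sign assignments applied to the observed midranks
  (this is the regime bootstrap resampling creates, since duplicated
  subjects contribute exactly tied differences);
* otherwise: normal approximation with continuity correction and the
  standard tie correction of the null variance.

Two-sided p-values are ``min(1, 2 * min(P(W <= w), P(W >= w)))`` under the
applicable null.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

EXACT_MAX = 25  # largest nonzero-pair count for the tie-free exact null
ENUM_MAX = 14   # largest nonzero-pair count for direct sign enumeration


@lru_cache(maxsize=64)
def _exact_cdf(n: int) -> np.ndarray:
    """CDF of W+ (sum of positive ranks) for n untied pairs: c[w] = P(W+ <= w)."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        # one knapsack pass per rank; RHS is evaluated before assignment
        counts[k:] = counts[k:] + counts[:-k]
    return np.cumsum(counts) / counts.sum()


@lru_cache(maxsize=16)
def _sign_matrix(n: int) -> np.ndarray:
    """(2^n, n) matrix of all 0/1 sign assignments."""
    bits = np.arange(1 << n, dtype=np.uint32)
    return ((bits[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.float64)


def _tie_term(ranks_row: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the nonzero midranks of one row."""
    r = ranks_row[ranks_row > 0]
    _, counts = np.unique(r, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def signed_rank_pvalues(diffs: np.ndarray) -> np.ndarray:
    """Two-sided paired Wilcoxon signed-rank p-values, one per row.

    Parameters
    ----------
    diffs:
        (n_genes, n_subjects) array of within-subject paired differences,
        or a 1-D array for a single gene.

    Returns
    -------
    1-D array of two-sided p-values.
    """
    D = np.atleast_2d(np.asarray(diffs, dtype=float))
    if D.ndim != 2:
        raise ValueError("diffs must be 1-D or 2-D")
    if not np.isfinite(D).all():
        raise ValueError("paired differences contain non-finite values")
    n_rows, n = D.shape
    if n < 1:
        raise ValueError("at least one paired difference is required")

    absD = np.abs(D)
    nonzero = absD > 0
    n_nz = nonzero.sum(axis=1)

    # midranks of |d| among the nonzero entries of each row; zeros rank 0.
    # Zeros sort strictly below every nonzero magnitude, so the full-row rank
    # of a nonzero entry minus the number of zeros is its rank among nonzero.
    r_full = sps.rankdata(absD, axis=1, method="average")
    ranks = np.where(nonzero, r_full - (n - n_nz)[:, None], 0.0)
    W = np.where(D > 0, ranks, 0.0).sum(axis=1)

    srt = np.sort(absD, axis=1)
    tied = ((np.diff(srt, axis=1) == 0) & (srt[:, 1:] > 0)).any(axis=1)

    p = np.ones(n_rows)

    # --- exact DP branch: untied rows with 1 <= n_nz <= EXACT_MAX
    dp_rows = ~tied & (n_nz >= 1) & (n_nz <= EXACT_MAX)
    for m in np.unique(n_nz[dp_rows]):
        idx = np.flatnonzero(dp_rows & (n_nz == m))
        cdf = _exact_cdf(int(m))
        w = np.rint(W[idx]).astype(np.int64)
        p_le = cdf[w]
        p_ge = np.where(w >= 1, 1.0 - cdf[np.maximum(w - 1, 0)], 1.0)
        p[idx] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))

    # --- enumeration branch: tied rows with n_nz <= ENUM_MAX
    enum_rows = tied & (n_nz <= ENUM_MAX)
    for m in np.unique(n_nz[enum_rows]):
        idx = np.flatnonzero(enum_rows & (n_nz == m))
        m = int(m)
        # null distribution of W+ depends only on the multiset of nonzero
        # midranks, so sorted top-m ranks suffice (zeros rank 0, nonzero >= 1)
        # doubled midranks are exact integers
        R2 = np.rint(2.0 * np.sort(ranks[idx], axis=1)[:, n - m:]).astype(np.int64)
        W2 = np.rint(2.0 * W[idx]).astype(np.int64)
        S = _sign_matrix(m)
        W_null = R2.astype(float) @ S.T  # (rows, 2^m), exact small integers
        p_le = (W_null <= W2[:, None]).mean(axis=1)
        p_ge = (W_null >= W2[:, None]).mean(axis=1)
        p[idx] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))

    # --- normal approximation: everything else with n_nz >= 1
    approx_rows = (n_nz >= 1) & ~dp_rows & ~enum_rows
    if approx_rows.any():
        idx = np.flatnonzero(approx_rows)
        m = n_nz[idx].astype(float)
        tie_terms = np.array([_tie_term(ranks[i]) for i in idx])
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_terms / 48.0
        d = W[idx] - mu
        # continuity correction toward the mean
        z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
        p[idx] = np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z)))

    return p


def signed_rank_test(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p-value for a single vector of paired differences."""
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("expected a 1-D vector of paired differences")
    return float(signed_rank_pvalues(d[None, :])[0])


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values with monotone enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bh_reject_count(pvals: np.ndarray, alpha: float) -> int:
    """Number of BH q-values strictly below alpha, without forming q.

    Equivalent to ``(bh_adjust(p) < alpha).sum()`` but cheaper; this is the
    inner statistic of every permutation and bootstrap draw.
    """
    ps = np.sort(np.asarray(pvals, dtype=float))
    m = ps.size
    if m == 0:
        return 0
    crit = alpha * np.arange(1, m + 1) / m
    hits = np.flatnonzero(ps < crit)
    return int(hits[-1] + 1) if hits.size else 0


def bh_reject_mask(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of BH rejections (q < alpha) at level alpha."""
    p = np.asarray(pvals, dtype=float)
    k = bh_reject_count(p, alpha)
    if k == 0:
        return np.zeros(p.size, dtype=bool)
    thresh = np.sort(p)[k - 1]
    return p <= thresh
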