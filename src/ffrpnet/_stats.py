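"""Shared statistical primitives used across the pipeline modules."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def rankdata_rows(x: np.ndarray) -> np.ndarray:
    """Midrank each row of a 2-D array (no NaN handling; caller masks)."""
    return stats.rankdata(x, axis=-1)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``x`` with the vector ``y``.

    Rows (or ``y``) with zero variance yield NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt(float((yc**2).sum()))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r[denom == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    return r


def spearman_rows_vs_vector(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``x`` with ``y``, pairwise-complete.

    Rows are grouped by their missingness pattern (joint with ``y``'s) so that
    ranks are recomputed on exactly the complete pairs for every row, which is
    the strict pairwise-complete definition, while staying vectorised.
    Rows with fewer than 3 complete pairs yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(x) & ~np.isnan(y)[None, :]
    out = np.full(x.shape[0], np.nan)
    # pack each row's mask into bytes for fast grouping
    packed = np.packbits(valid, axis=1)
    _, inverse = np.unique(packed, axis=0, return_inverse=True)
    for gid in np.unique(inverse):
        rows = np.nonzero(inverse == gid)[0]
        cols = np.nonzero(valid[rows[0]])[0]
        if cols.size < 3:
            continue
        rx = rankdata_rows(x[np.ix_(rows, cols)])
        ry = stats.rankdata(y[cols])
        out[rows] = pearson_rows(rx, ry)
    return out


def pearson_rows_vs_vector(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson analogue of :func:`spearman_rows_vs_vector` (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(x) & ~np.isnan(y)[None, :]
    out = np.full(x.shape[0], np.nan)
    packed = np.packbits(valid, axis=1)
    _, inverse = np.unique(packed, axis=0, return_inverse=True)
    for gid in np.unique(inverse):
        rows = np.nonzero(inverse == gid)[0]
        cols = np.nonzero(valid[rows[0]])[0]
        if cols.size < 3:
            continue
        out[rows] = pearson_rows(x[np.ix_(rows, cols)], y[cols])
    return out


from functools import lru_cache


@lru_cache(maxsize=None)
def _exact_abs_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null), n <= 9."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    sumd2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1 - 6 * sumd2 / (n**3 - n)
    return np.sort(np.abs(rho))


def spearman_pair(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9):
    """Spearman rho and p-value for one pair, pairwise-complete.

    The p-value uses the large-sample t approximation, except for small
    tie-free samples (n <= ``exact_max_n``) where the exact permutation
    distribution of rho is used (two-sided, as-or-more-extreme in |rho|).
    Returns (rho, pvalue, n_complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rho = float(pearson_rows(rx[None, :], ry)[0])
    if np.isnan(rho):
        return rho, np.nan, n
    tie_free = (np.unique(rx).size == n) and (np.unique(ry).size == n)
    if n <= exact_max_n and tie_free:
        null = _exact_abs_rho_null(n)
        count = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return rho, count / null.size, n
    # t approximation
    if abs(rho) >= 1.0:
        return rho, 0.0, n
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i} m*p_(j)/j, capped at 1.

    Raises ValueError for p-values outside (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def stouffer_combine(pvalues) -> float:
    """Combine one-sided p-values by Stouffer's Z-score method.

    z_i = Phi^{-1}(1 - p_i), Z = sum(z_i)/sqrt(k), combined p = 1 - Phi(Z).
    NaN entries are dropped; p-values are clipped away from {0, 1} so the
    normal quantile stays finite.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = 1e-300
    p = np.clip(p, tiny, 1 - 1e-16)
    z = stats.norm.isf(p)
    Z = z.sum() / math.sqrt(p.size)
    return float(stats.norm.sf(Z))


def hypergeom_overlap_p(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for overlap ``k`` of two gene sets."""
    return float(stats.hypergeom.sf(k - 1, n_universe, n_a, n_b))


def exact_rank_sum_p(x, y, alternative: str = "less") -> float:
    """Exact-conditional one/two-sided rank-sum p for small samples.

    Assigns midranks to the pooled sample (ties allowed) and enumerates all
    C(n1+n2, n1) assignments of ranks to group one, conditioning on the
    observed tie pattern.  The statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    obs = ranks[:n1].sum()
    count = 0
    total = 0
    eps = 1e-9
    for combo in itertools.combinations(range(pooled.size), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if alternative == "less":
            if s <= obs + eps:
                count += 1
        elif alternative == "greater":
            if s >= obs - eps:
                count += 1
        elif alternative == "two-sided":
            # distance from the null mean of the rank sum
            mu = n1 * (pooled.size + 1) / 2
            if abs(s - mu) >= abs(obs - mu) - eps:
                count += 1
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return count / total
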