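"""Rank statistics for atlas identity mapping.

Two primitives drive the mapping stage: a Spearman correlation computed
from per-profile gene ranks (the rank-difference formula in the tie-free
case, Pearson on ranks otherwise) and a Wilcoxon rank-sum test that asks
whether one set of correlation coefficients sits above a background set.
The rank-sum test uses exact enumeration of the null distribution for
small tie-free inputs and a tie-corrected, continuity-corrected normal
approximation otherwise.
"""
from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateInputError, UndefinedCorrelationError

#: Largest combined sample size for which the exact rank-sum null
#: distribution is enumerated (tie-free inputs only).
EXACT_MAX_N = 25


def rank_profile(values) -> np.ndarray:
    """Rank a single expression profile, averaging tied ranks.

    Returns ranks 1..n whose sum is n(n+1)/2. Missing or non-finite
    values are rejected: filtering belongs upstream of ranking.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rank_profile expects a 1-D vector")
    if arr.size < 2:
        raise ValueError("profile must contain at least two values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("profile contains missing/non-finite values")
    return _sps.rankdata(arr, method="average")


def spearman_rho(x_ranks, y_ranks) -> float:
    """Spearman coefficient from two rank vectors.

    Without ties this is the classical rank-difference form
    ``1 - 6 * sum(d^2) / (n (n^2 - 1))``; with ties it is the Pearson
    correlation of the rank vectors (the two coincide when tie-free).
    """
    x = np.asarray(x_ranks, dtype=float)
    y = np.asarray(y_ranks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("rank vectors must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired ranks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero rank variance in a profile")
    if _tie_free(x, n) and _tie_free(y, n):
        d = x - y
        rho = 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1.0))
    else:
        xc = x - x.mean()
        yc = y - y.mean()
        rho = float(xc @ yc) / np.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(min(1.0, max(-1.0, rho)))


def _tie_free(r: np.ndarray, n: int) -> bool:
    # average-tie ranks of a tie-free vector are exactly a permutation of 1..n
    return np.unique(r).size == n


def wilcoxon_rank_sum(category_values, background_values,
                      alternative: str = "greater") -> tuple[float, float]:
    """Rank-sum test of ``category`` against ``background``.

    Returns ``(w, p)`` where ``w`` is the rank sum of the category values
    in the pooled sample. ``alternative='greater'`` tests whether the
    category values are stochastically larger than the background.

    The exact permutation null is enumerated when the pooled sample has
    at most :data:`EXACT_MAX_N` values and no ties; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction is
    used. A pooled sample with zero variance yields p = 1.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    x = np.asarray(category_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("category and background must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("rank-sum inputs must be finite")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = _sps.rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())
    _, counts = np.unique(pooled, return_counts=True)
    tie_free = counts.size == n
    if n <= EXACT_MAX_N and tie_free:
        p = _exact_ranksum_p(int(round(w)), n1, n, alternative)
    else:
        p = _normal_ranksum_p(w, n1, n2, counts, alternative)
    return w, float(min(1.0, max(p, 5e-324)))


def exact_ranksum_distribution(n1: int, n: int) -> np.ndarray:
    """Counts of tie-free rank-sum values for ``n1`` of ``n`` ranks.

    Entry ``s`` of the returned vector is the number of n1-subsets of
    {1..n} whose ranks sum to ``s`` (entries below the minimal sum are 0).
    """
    max_s = n1 * n
    f = np.zeros((n1 + 1, max_s + 1))
    f[0, 0] = 1.0
    for i in range(1, n + 1):
        for k in range(min(i, n1), 0, -1):
            f[k, i:] += f[k - 1, : max_s + 1 - i]
    return f[n1]


def _exact_ranksum_p(w: int, n1: int, n: int, alternative: str) -> float:
    counts = exact_ranksum_distribution(n1, n)
    total = comb(n, n1)
    p_ge = counts[w:].sum() / total
    if alternative == "greater":
        return p_ge
    p_le = counts[: w + 1].sum() / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def _normal_ranksum_p(w: float, n1: int, n2: int, tie_counts: np.ndarray,
                      alternative: str) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(((tie_counts ** 3) - tie_counts).sum()) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 1.0  # all pooled values identical: no evidence either way
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        return float(_sps.norm.sf(z))
    z = (abs(w - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * _sps.norm.sf(max(z, 0.0))))


def pooled_ttest(a, b, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test; returns ``(t, df, p)``.

    Defaults to the pooled-variance Student form; ``equal_var=False``
    switches to Welch with Satterthwaite degrees of freedom.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    na, nb = x.size, y.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two values per group")
    va = float(x.var(ddof=1))
    vb = float(y.var(ddof=1))
    diff = float(x.mean() - y.mean())
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        sea2, seb2 = va / na, vb / nb
        se = np.sqrt(sea2 + seb2)
        if sea2 + seb2 > 0:
            df = (sea2 + seb2) ** 2 / (
                sea2 ** 2 / (na - 1) + seb2 ** 2 / (nb - 1))
        else:
            df = na + nb - 2
    if se == 0:
        if diff == 0:
            return 0.0, float(df), 1.0
        raise DegenerateInputError(
            "zero within-group variance with unequal means")
    t = diff / se
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return float(t), float(df), min(1.0, p)
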