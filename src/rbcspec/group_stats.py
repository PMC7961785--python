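"""Nonparametric two-group comparison and box-plot summaries.

The Mann-Whitney U test is implemented from first principles: U from
midranks, and the exact two-sided p-value from the full permutation null
distribution conditional on the observed (possibly tied) pooled values.
The null distribution is built by a subset-sum dynamic program over doubled
midranks (integers even with .5 midranks), which is exact and fast for the
sample sizes where the exact test is used (n1+n2 <= 20 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import shapiro as _scipy_shapiro

from rbcspec.errors import InputError

__all__ = [
    "GroupComparison",
    "BoxSummary",
    "mann_whitney_u",
    "shapiro_wilk",
    "box_summary",
    "stars",
    "benjamini_hochberg",
]

EXACT_MAX_N = 20  # exact enumeration used whenever n1 + n2 <= this


@dataclass(frozen=True)
class GroupComparison:
    n1: int
    n2: int
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    stars: str
    p_less: float = float("nan")  # P(shift of y below x); one-sided
    p_greater: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise InputError(f"U={self.U} outside [0, {self.n1 * self.n2}]")
        if not (0 < self.p_two_sided <= 1):
            raise InputError(f"invalid p-value {self.p_two_sided}")


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise InputError("box summary ordering violated")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x (number of (x_i, y_j) pairs with x_i > y_j, ties count 1/2)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


@lru_cache(maxsize=128)
def _null_counts(doubled_ranks: tuple[int, ...], n1: int) -> tuple[np.ndarray, int]:
    """Distribution of the group-1 doubled-rank sum over all labelings.

    Returns (counts, total) where counts[s] is the number of n1-subsets of
    the pooled sample whose doubled-midrank sum equals s; doubled midranks
    are small positive integers even when midranks end in .5.
    """
    total = sum(doubled_ranks)
    # dp[k][s] = number of k-subsets with doubled-rank sum s (0/1 knapsack)
    dp = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for v in doubled_ranks:
        for k in range(n1, 0, -1):  # k descending: each item used once
            dp[k, v:] += dp[k - 1, : total + 1 - v]
    counts = dp[n1]
    return counts, total


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p: null probability of |U - n1*n2/2| >= |u_obs - n1*n2/2|.

    The null distribution of U is enumerated exactly, conditional on the
    pooled values (ties included), via a subset-sum DP over doubled midranks.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    doubled = tuple(int(round(2 * r)) for r in sorted(ranks))
    counts, _ = _null_counts(doubled, n1)
    total_labelings = math.comb(n1 + n2, n1)
    # doubled rank sum S relates to U by U = S/2 - n1(n1+1)/2
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    s_values = np.nonzero(counts)[0]
    u_values = s_values / 2.0 - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    extreme = np.abs(u_values - mu) >= dev - eps
    hits = int(counts[s_values[extreme]].sum())
    return hits / total_labelings


def _exact_one_sided(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """(P(U <= u_obs), P(U >= u_obs)) under the exact null."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    doubled = tuple(int(round(2 * r)) for r in sorted(rankdata(pooled)))
    counts, _ = _null_counts(doubled, n1)
    total_labelings = math.comb(n1 + n2, n1)
    s_values = np.nonzero(counts)[0]
    u_values = s_values / 2.0 - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    p_le = int(counts[s_values[u_values <= u_obs + eps]].sum()) / total_labelings
    p_ge = int(counts[s_values[u_values >= u_obs - eps]].sum()) / total_labelings
    return p_le, p_ge


def _normal_approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float, float]:
    """Two-sided and one-sided p by normal approximation with tie and
    continuity corrections."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0, 1.0, 1.0
    sd = math.sqrt(var)
    z = (abs(u_obs - mu) - 0.5) / sd
    p_two = min(1.0, 2.0 * float(_norm.sf(max(z, 0.0))))
    z_le = (u_obs - mu + 0.5) / sd
    z_ge = (u_obs - mu - 0.5) / sd
    return p_two, float(_norm.cdf(z_le)), float(_norm.sf(z_ge))


def mann_whitney_u(
    x: np.ndarray | list, y: np.ndarray | list, method: str = "auto"
) -> GroupComparison:
    """Mann-Whitney U test of two independent samples.

    Parameters
    ----------
    x, y : array-like
        The two samples (x = group 1; U counts pairs x_i > y_j, ties 1/2).
    method : {"auto", "exact", "normal_approx"}
        ``auto`` uses the exact permutation distribution when
        n1 + n2 <= 20, the normal approximation otherwise.

    Returns
    -------
    GroupComparison
        Two-sided p defined as the exact null probability of
        |U - n1*n2/2| >= |u_obs - n1*n2/2|; one-sided tail probabilities in
        ``p_less`` / ``p_greater``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("mann_whitney_u requires non-empty samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in samples")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if method not in {"auto", "exact", "normal_approx"}:
        raise InputError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= EXACT_MAX_N)
    if use_exact:
        p_two = _exact_two_sided_p(x, y, u_obs)
        p_le, p_ge = _exact_one_sided(x, y, u_obs)
        used = "exact"
    else:
        p_two, p_le, p_ge = _normal_approx_p(x, y, u_obs)
        used = "normal_approx"
    return GroupComparison(
        n1=n1, n2=n2, U=u_obs, p_two_sided=p_two,
        method=used, stars=stars(p_two), p_less=p_le, p_greater=p_ge,
    )


def shapiro_wilk(x: np.ndarray | list) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise InputError(f"shapiro_wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise InputError("shapiro_wilk requires a non-constant sample")
    res = _scipy_shapiro(x)
    return float(res.statistic), float(res.pvalue)


def box_summary(x: np.ndarray | list) -> BoxSummary:
    """Box-plot statistics: median, quartiles by linear interpolation,
    min-max whiskers."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("box_summary requires a non-empty sample")
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite values in sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(x.min()), max=float(x.max()), n=int(x.size),
    )


def stars(p: float) -> str:
    """Significance stars: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if not (0 <= p <= 1):
        raise InputError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def benjamini_hochberg(pvals: np.ndarray | list) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj
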