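"""Statistical procedures used throughout the pipeline.

Every test here mirrors the corresponding base-R behaviour (``prop.test``,
``wilcox.test``, ``cor.test``): two-sided p-values, Yates continuity
correction for the 2-sample proportion test, midranks for ties.  The Wilson
score interval is written out in closed form so that the endpoints collapse
exactly to 0 at k=0 and to 1 at k=n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilson_interval",
    "two_proportion_test",
    "mann_whitney_u",
    "rank_correlation",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``estimate`` carries the method's natural effect size (difference of
    proportions, U statistic location shift, or a correlation coefficient).
    """

    statistic: float
    p_value: float
    method: str
    estimate: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Parameters
    ----------
    k : number of successes, ``0 <= k <= n``.
    n : number of trials, ``>= 1``.
    confidence : two-sided coverage, default 0.95.

    Returns
    -------
    (low, high) bounds; ``low == 0`` exactly when ``k == 0`` and
    ``high == 1`` exactly when ``k == n``.
    """
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2.0 * n)
    half = z * sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    low = (centre - half) / denom
    high = (centre + half) / denom
    # the closed form is exact at the boundary; clamp away rounding dust
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return max(0.0, low), min(1.0, high)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """2-sample test for equality of proportions with continuity correction.

    Yates-corrected chi-square on the 2x2 table, one degree of freedom,
    identical to R's ``prop.test(c(k1, k2), c(n1, n2))``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    total = n1 + n2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate 2x2 table: a marginal total is zero")
    diff = abs(a * d - b * c)
    corr = min(diff, total / 2.0)  # floor the corrected statistic at zero
    chi2 = total * (diff - corr) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return TestResult(
        statistic=chi2,
        p_value=min(1.0, p),
        method="2-sample test for equality of proportions with continuity correction",
        estimate=k1 / n1 - k2 / n2,
    )


def _mwu_exact_p(ranks_sum_a: float, ranks: np.ndarray, n_a: int, alternative: str) -> float:
    """Exact p by enumerating all assignments of ranks to group A.

    Ties are handled by enumerating over the observed midranks, so the null
    distribution conditions on the tie pattern (the standard exact treatment).
    """
    n = len(ranks)
    mean_w = n_a * (n + 1) / 2.0
    obs_dev = abs(ranks_sum_a - mean_w)
    hits = 0
    total = comb(n, n_a)
    eps = 1e-12
    for idx in combinations(range(n), n_a):
        w = float(ranks[list(idx)].sum())
        if alternative == "two-sided":
            hit = abs(w - mean_w) >= obs_dev - eps
        elif alternative == "greater":
            hit = w >= ranks_sum_a - eps
        else:  # less
            hit = w <= ranks_sum_a + eps
        hits += hit
    return hits / total


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact enumeration of the rank-assignment null when both groups have at
    most 8 observations; otherwise the normal approximation with tie
    correction and continuity correction.  ``alternative`` is "two-sided"
    (default), "greater" (A tends larger) or "less".
    """
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    n_a, n_b = a.size, b.size
    w_a = float(ranks[:n_a].sum())
    u_a = w_a - n_a * (n_a + 1) / 2.0  # U for group A

    if n_a <= 8 and n_b <= 8:
        p = _mwu_exact_p(w_a, ranks, n_a, alternative)
        method = "Mann-Whitney U test (exact)"
    else:
        mean_u = n_a * n_b / 2.0
        n = n_a + n_b
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return TestResult(u_a, 1.0, "Mann-Whitney U test (normal approximation)", u_a)
        sd = sqrt(var_u)
        if alternative == "two-sided":
            z = max((abs(u_a - mean_u) - 0.5) / sd, 0.0)
            p = erfc(z / sqrt(2.0))
        elif alternative == "greater":
            p = float(sps.norm.sf((u_a - mean_u - 0.5) / sd))
        else:
            p = float(sps.norm.cdf((u_a - mean_u + 0.5) / sd))
        method = "Mann-Whitney U test (normal approximation)"
    return TestResult(statistic=u_a, p_value=min(1.0, p), method=method, estimate=u_a)


def rank_correlation(x: Sequence[float], y: Sequence[float], method: str = "spearman") -> TestResult:
    """Spearman or Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        name = "Pearson correlation"
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
        name = "Spearman rank correlation"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(r), p_value=float(min(1.0, p)), method=name, estimate=float(r))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; reports are raw by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj
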