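"""Shared statistical primitives: Mann-Whitney U, BH FDR, hypergeometric tail.

Thin, validated wrappers around scipy/statsmodels that fix the conventions
used throughout the package (exact vs. normal-approximation switching,
step-up FDR, upper-tail hypergeometric) and carry a uniform result type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: significance annotation thresholds, rendered as in standard reports
_LADDER = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

#: largest pooled sample size for which the exact U distribution is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str  # {"exact", "normal-approx"}
    n1: int
    n2: int

    def stars(self) -> str:
        return significance_ladder(self.p)


def significance_ladder(p: float) -> str:
    """Render a p-value as the conventional star ladder (ns/*/**/***/****)."""
    for cut, stars in _LADDER:
        if p < cut:
            return stars
    return "ns"


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Rank-based two-sample Mann-Whitney U test.

    Uses the exact permutation distribution when the pooled sample size is
    at most :data:`EXACT_LIMIT` and the data are tie-free; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.  The statistic is U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= EXACT_LIMIT and not ties
    res = sps.mannwhitneyu(
        x, y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal-approx",
        n1=int(x.size),
        n2=int(y.size),
    )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` successes in the population, ``n`` draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))
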