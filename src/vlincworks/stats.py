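"""Exact and rank-based statistics shared across the pipeline.

Enrichment tests default to one-sided "greater" — the direction of every
enrichment claim made downstream.  All p-values lie in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: sentinel for a correlation that cannot be computed (constant input)
NOT_COMPUTABLE = float("nan")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = category, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in contingency table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


def fisher_exact_one_sided(t: ContingencyTable2x2, direction: str = "greater") -> float:
    """One-sided Fisher exact test: hypergeometric tail P(X >= a) given margins.

    'greater' asks whether the first row is enriched for the first column.
    Degenerate margins give p = 1.
    """
    N = t.a + t.b + t.c + t.d
    K = t.a + t.b  # row-1 margin
    n = t.a + t.c  # col-1 margin
    if K == 0 or n == 0 or K == N or n == N:
        return 1.0
    if direction == "greater":
        return float(sps.hypergeom.sf(t.a - 1, N, K, n))
    if direction == "less":
        return float(sps.hypergeom.cdf(t.a, N, K, n))
    if direction == "two-sided":
        return float(sps.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])
    raise ValueError(f"bad direction {direction!r}")


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Upper-tail hypergeometric P(X >= k) and the expected count n*K/N.

    N population, K marked in population, n drawn, k marked among drawn.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent population parameters")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"impossible observed count k={k} for N={N},K={K},n={n}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0), n * K / N


def binomial_upper_tail(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return float(sps.binom.sf(k - 1, n, p))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho on average ranks; NaN sentinel when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return NOT_COMPUTABLE
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rowwise-vs-rowwise Spearman: result[i, j] = rho(A[i], B[j]).

    Constant rows yield NaN columns/rows.  Both matrices share the sample
    axis (columns).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("sample dimensions differ")

    def ranked(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        R = np.apply_along_axis(sps.rankdata, 1, M)
        R -= R.mean(axis=1, keepdims=True)
        norm = np.sqrt((R * R).sum(axis=1))
        const = norm == 0
        norm[const] = 1.0
        return R / norm[:, None], const

    RA, constA = ranked(A)
    RB, constB = ranked(B)
    C = RA @ RB.T
    C[constA, :] = np.nan
    C[:, constB] = np.nan
    return C


def ks_one_sided(a: Sequence[float], b: Sequence[float], alternative: str = "greater") -> float:
    """One-sided two-sample KS p-value.

    ``alternative='greater'`` tests whether *a* is stochastically greater
    than *b* (i.e. the CDF of *a* lies below that of *b*).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    # scipy's 'less' means CDF(a) < CDF(b), i.e. a stochastically greater
    alt = {"greater": "less", "less": "greater", "two-sided": "two-sided"}[alternative]
    return float(sps.ks_2samp(a, b, alternative=alt).pvalue)


def mww_one_sided(a: Sequence[float], b: Sequence[float], alternative: str = "greater") -> float:
    """One-sided Mann-Whitney-Wilcoxon p-value; 'greater' = a shifted above b."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    return float(sps.mannwhitneyu(a, b, alternative=alternative).pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; empty in, empty out."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def empirical_perm_p(observed: float, null_draws: Sequence[float]) -> float:
    """Permutation p with the (r + 1)/(n + 1) estimator; never exactly 0."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("no null draws")
    r = int(np.sum(null_draws >= observed))
    return (r + 1) / (null_draws.size + 1)
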