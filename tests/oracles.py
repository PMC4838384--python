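"""Independent brute-force oracles used across the suite.

Each oracle recomputes an operation's result from first principles
(per-base boolean arrays, exhaustive scans, naive definitions) without
touching the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from vlincworks.intervals import GenomicInterval


def masked_residual_per_base(target, masks, strand_rule):
    """Residual unmasked length by explicit per-base flags."""
    covered = np.zeros(target.length, dtype=bool)
    for m in masks:
        if m.chrom != target.chrom:
            continue
        if strand_rule == "same_strand" and m.strand != target.strand:
            continue
        lo = max(m.start, target.start) - target.start
        hi = min(m.end, target.end) - target.start
        if lo < hi:
            covered[lo:hi] = True
    return int((~covered).sum())


def separated_scan(a, b, insulators):
    """Exhaustive per-insulator scan of the wholly-within-gap rule."""
    if a.start < b.start:
        left, right = a, b
    else:
        left, right = b, a
    gap_start, gap_end = left.end, right.start
    if gap_start >= gap_end:
        return False
    for ins in insulators:
        if ins.chrom == a.chrom and ins.start >= gap_start and ins.end <= gap_end:
            return True
    return False


def merged_base_sets(intervals):
    """Per-(chrom, strand) sets of covered bases."""
    out = {}
    for iv in intervals:
        out.setdefault((iv.chrom, iv.strand), set()).update(
            range(iv.start, iv.end)
        )
    return out


def count_tags_double_loop(tags, fragments):
    """Naive double loop over (tag, fragment) with strand matching."""
    total = 0
    for chrom, pos, strand, count in tags:
        for f in fragments:
            if (
                f.chrom == chrom
                and f.strand == strand
                and f.start <= pos < f.end
            ):
                total += count
                break
    return total


def classify_by_end_distances(a, b):
    """Configuration from explicit end positions, independent re-derivation."""
    if a.strand == b.strand:
        a_mid = (a.start + a.end) / 2
        b_mid = (b.start + b.end) / 2
        if b.end <= a.start:
            b_left = True
        elif b.start >= a.end:
            b_left = False
        else:
            b_left = b_mid < a_mid
        if a.strand == "+":
            return "same_upstream" if b_left else "same_downstream"
        return "same_downstream" if b_left else "same_upstream"
    a5 = a.start if a.strand == "+" else a.end - 1
    a3 = a.end - 1 if a.strand == "+" else a.start
    b5 = b.start if b.strand == "+" else b.end - 1
    b3 = b.end - 1 if b.strand == "+" else b.start
    return (
        "opposite_head_to_head"
        if abs(a5 - b5) <= abs(a3 - b3)
        else "opposite_tail_to_tail"
    )


def two_stage_median_naive(values_by_feature):
    firsts = []
    for vals in values_by_feature.values():
        clean = sorted(v for v in vals if not math.isnan(v))
        if clean:
            n = len(clean)
            firsts.append(
                clean[n // 2] if n % 2 else (clean[n // 2 - 1] + clean[n // 2]) / 2
            )
    if not firsts:
        return float("nan")
    firsts.sort()
    n = len(firsts)
    return firsts[n // 2] if n % 2 else (firsts[n // 2 - 1] + firsts[n // 2]) / 2


def bh_naive(pvals):
    """Direct O(m^2) BH definition: adj_i = min over {j: p_j >= p_i} of p_j*m/rank_j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        candidates = [
            pvals[order[r - 1]] * m / r for r in range(rank, m + 1)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def hypergeom_tail_enumerate(N, K, n, k):
    """Upper tail by explicit summation of hypergeometric pmf terms."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total


def binom_tail_factorial(n, k, p):
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)
    )


def mww_enumerate(a, b):
    """Exact one-sided (a greater) MWW p by enumerating group assignments."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(sel):
        sa = [pooled[i] for i in sel]
        sb = [pooled[i] for i in range(len(pooled)) if i not in set(sel)]
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in sa for y in sb
        )

    observed = sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
    )
    hits = 0
    total = 0
    for sel in combinations(range(len(pooled)), na):
        total += 1
        if u_stat(sel) >= observed - 1e-12:
            hits += 1
    return hits / total
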