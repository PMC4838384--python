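"""Neighbor-pair configuration, distance binning and correlation tables.

Each stranded feature-gene pair falls into one of four geometric
configurations — same-strand with the gene upstream or downstream of the
feature, or opposite-strand head-to-head (facing 5' ends) or tail-to-tail
(facing 3' ends) — and one of eight distance bins.  Co-expression is
summarised per (configuration, bin) as a two-stage median of Spearman
correlations: per-feature median over its neighbours first, then the median
across features.  Stratifying the same table by insulator separation is
what lets shared-chromatin correlation be told apart from a cis-activating
effect of the transcript itself.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TranscriptModel, separated_by_insulator
from .quantify import ExpressionMatrix
from .stats import ks_one_sided, mww_one_sided, spearman

SAME_UPSTREAM = "same_upstream"
SAME_DOWNSTREAM = "same_downstream"
OPP_TAIL = "opposite_tail_to_tail"
OPP_HEAD = "opposite_head_to_head"
CONFIGURATIONS = (SAME_UPSTREAM, SAME_DOWNSTREAM, OPP_TAIL, OPP_HEAD)

#: right edges of the distance bins (bp); distances beyond the last edge
#: fall into the open '>50 kb' bin
BIN_EDGES = (1_000, 5_000, 10_000, 20_000, 30_000, 40_000, 50_000)
BIN_LABELS = ("0-1kb", "1-5kb", "5-10kb", "10-20kb", "20-30kb", "30-40kb",
              "40-50kb", ">50kb")

STRATA = ("all", "separated", "not_separated")


@dataclass(frozen=True)
class NeighborPair:
    a_id: str
    b_id: str
    pair_type: str  # 'vlinc-gene' | 'gene-gene'
    configuration: str
    distance: int
    bin: str
    insulator_separated: bool


def distance_bin(distance: int) -> str:
    """Bin label for a gap; bins are left-inclusive, right-exclusive."""
    return BIN_LABELS[bisect_right(BIN_EDGES, distance)]


def classify_pair(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[str, int, str]:
    """Configuration, nearest-end gap and distance bin for a stranded pair.

    Same-strand pairs: the configuration names where the gene *b* sits in
    *a*'s transcriptional orientation.  Opposite-strand pairs are
    head-to-head when the 5' ends are the nearer pair of ends (ties break
    toward head-to-head), else tail-to-tail.  Overlapping pairs get
    distance 0 and the closest bin.
    """
    if a.chrom != b.chrom:
        raise ValueError("pair spans chromosomes")
    if a.strand == ".":
        raise ValueError("first interval needs a resolved strand")
    distance = a.gap_to(b)
    if a.strand == b.strand:
        if b.end <= a.start:
            b_is_left = True
        elif b.start >= a.end:
            b_is_left = False
        else:  # overlap: fall back to midpoints
            b_is_left = (b.start + b.end) < (a.start + a.end)
        upstream = b_is_left if a.strand == "+" else not b_is_left
        config = SAME_UPSTREAM if upstream else SAME_DOWNSTREAM
    else:
        d_head = abs(a.five_prime() - b.five_prime())
        d_tail = abs(a.three_prime() - b.three_prime())
        config = OPP_HEAD if d_head <= d_tail else OPP_TAIL
    return config, distance, distance_bin(distance)


def nearest_neighbor_sets(
    features_a: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    pair_type: str,
    insulators: Sequence[GenomicInterval] = (),
    horizon: int = 200_000,
) -> list[NeighborPair]:
    """All feature-gene pairs with gap <= horizon, classified and stratified.

    The horizon bounds the open '>50 kb' bin so the pair set stays finite.
    Self-pairs and unresolved-strand genes are skipped; a feature near a
    chromosome edge simply lacks pairs on that side.
    """
    genes_by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        if g.strand != ".":
            genes_by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[NeighborPair] = []
    for feat in features_a:
        if feat.strand == ".":
            continue
        for g in genes_by_chrom.get(feat.chrom, []):
            if g.id == feat.id:
                continue
            if feat.body.gap_to(g.body) > horizon:
                continue
            config, dist, label = classify_pair(feat.body, g.body)
            sep = separated_by_insulator(feat.body, g.body, insulators)
            pairs.append(
                NeighborPair(feat.id, g.id, pair_type, config, dist, label, sep)
            )
    return pairs


def pair_correlations(
    expr: ExpressionMatrix, pairs: Sequence[NeighborPair]
) -> dict[tuple[str, str], float]:
    """Spearman rho across samples per pair; NaN for constant rows."""
    out: dict[tuple[str, str], float] = {}
    for p in pairs:
        key = (p.a_id, p.b_id)
        if key in out:
            continue
        if p.a_id not in expr.values.index or p.b_id not in expr.values.index:
            out[key] = float("nan")
            continue
        out[key] = spearman(expr.row(p.a_id), expr.row(p.b_id))
    return out


def two_stage_median(values_by_feature: Mapping[str, Sequence[float]]) -> float:
    """Median over features of each feature's median rho (NaNs dropped)."""
    per_feature = []
    for vals in values_by_feature.values():
        clean = [v for v in vals if not math.isnan(v)]
        if clean:
            per_feature.append(float(np.median(clean)))
    return float(np.median(per_feature)) if per_feature else float("nan")


def correlation_table(
    expr: ExpressionMatrix,
    pairs: Sequence[NeighborPair],
    min_features: int = 3,
) -> pd.DataFrame:
    """Long-format table of two-stage median rho per
    (pair_type, configuration, bin, insulator stratum).

    Cells backed by fewer than *min_features* features report NaN but keep
    their counts, so sparse strata stay visible without asserting a median.
    """
    rhos = pair_correlations(expr, pairs)
    rows = []
    pair_types = sorted({p.pair_type for p in pairs})
    for pt in pair_types:
        for config in CONFIGURATIONS:
            for label in BIN_LABELS:
                cell = [
                    p for p in pairs
                    if p.pair_type == pt and p.configuration == config
                    and p.bin == label
                ]
                for stratum in STRATA:
                    if stratum == "separated":
                        sel = [p for p in cell if p.insulator_separated]
                    elif stratum == "not_separated":
                        sel = [p for p in cell if not p.insulator_separated]
                    else:
                        sel = cell
                    by_feat: dict[str, list[float]] = {}
                    for p in sel:
                        by_feat.setdefault(p.a_id, []).append(
                            rhos[(p.a_id, p.b_id)]
                        )
                    n_feat = sum(
                        1 for v in by_feat.values()
                        if any(not math.isnan(x) for x in v)
                    )
                    med = (
                        two_stage_median(by_feat)
                        if n_feat >= min_features
                        else float("nan")
                    )
                    rows.append(
                        {
                            "pair_type": pt,
                            "configuration": config,
                            "bin": label,
                            "stratum": stratum,
                            "median_rho": med,
                            "n_pairs": len(sel),
                            "n_features": n_feat,
                        }
                    )
    return pd.DataFrame(rows)


def compare_pair_groups(
    rhos_a: Sequence[float],
    rhos_b: Sequence[float],
    test: str = "mww_one_sided",
) -> dict:
    """One-sided test that group *a*'s correlations exceed group *b*'s."""
    a = [r for r in rhos_a if not math.isnan(r)]
    b = [r for r in rhos_b if not math.isnan(r)]
    if test == "mww_one_sided":
        p = mww_one_sided(a, b, "greater")
    elif test == "ks_one_sided":
        p = ks_one_sided(a, b, "greater")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"p": p, "n_a": len(a), "n_b": len(b), "direction": "a_greater"}
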