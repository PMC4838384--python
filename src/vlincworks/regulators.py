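"""miRNA-target coupling, TF-vlincRNA time-course correlation, and
ChIP-seq flank enrichment against random genomic regions.

miRNAs serve as the positive control for reading regulator-target
relationships out of a large expression compendium: the primary miRNA
precursor is proxied by tags in a +/-1 kb window around the pre-miRNA
locus, and its validated targets should correlate negatively with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import LTR, NONLTR, NO_PROMOTER, VlincAnnotation
from .intervals import GenomicInterval
from .quantify import ExpressionMatrix, TagSet
from .stats import empirical_perm_p, ks_one_sided, spearman

SURROGATE_FLANK = 1_000


@dataclass(frozen=True)
class MirnaRecord:
    mirna_id: str
    pre_interval: GenomicInterval
    validated_targets: tuple[str, ...]

    @property
    def surrogate_window(self) -> GenomicInterval:
        iv = self.pre_interval
        return GenomicInterval(
            iv.chrom, max(0, iv.start - SURROGATE_FLANK), iv.end + SURROGATE_FLANK,
            iv.strand, self.mirna_id,
        )


@dataclass(frozen=True)
class CorrelationSummary:
    id: str
    median_rho_real: float
    median_rho_random: float
    n_targets_used: int


def mirna_surrogate_expression(
    tagsets: Sequence[TagSet], mirnas: Sequence[MirnaRecord]
) -> pd.DataFrame:
    """Sense-strand tag counts in each miRNA's +/-1 kb surrogate window,
    scaled per million informative reads (window lengths are uniform, so
    length scaling is immaterial for rank statistics)."""
    data = np.zeros((len(mirnas), len(tagsets)))
    for j, ts in enumerate(tagsets):
        for i, m in enumerate(mirnas):
            w = m.surrogate_window
            raw = ts.count_in(w.chrom, w.start, w.end, w.strand)
            data[i, j] = raw / ts.informative_reads * 1e6
    return pd.DataFrame(
        data, index=[m.mirna_id for m in mirnas],
        columns=[ts.sample_id for ts in tagsets],
    )


def mirna_target_profile(
    gene_expr: ExpressionMatrix,
    mirna_expr: pd.DataFrame,
    mirnas: Sequence[MirnaRecord],
    seed: int = 0,
) -> tuple[list[CorrelationSummary], float, int]:
    """Per-miRNA median Spearman rho over validated targets vs an equal-size
    random draw of expressed genes; one-sided KS p that real medians lie
    below random ones.

    miRNAs and targets must be expressed (non-zero in >= 1 sample); miRNAs
    left with no usable target are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [
        fid for fid in gene_expr.values.index
        if gene_expr.feature_kind[fid] == "gene"
        and gene_expr.values.loc[fid].to_numpy().any()
    ]
    gene_pool = np.array(gene_ids)
    summaries: list[CorrelationSummary] = []
    n_dropped = 0
    for m in mirnas:
        if m.mirna_id not in mirna_expr.index:
            n_dropped += 1
            continue
        mvec = mirna_expr.loc[m.mirna_id].to_numpy(dtype=float)
        if not mvec.any():
            n_dropped += 1
            continue
        targets = [t for t in m.validated_targets if t in set(gene_ids)]
        rhos = [
            r
            for t in targets
            if not math.isnan(r := spearman(mvec, gene_expr.row(t)))
        ]
        if not rhos:
            n_dropped += 1
            continue
        draw = rng.choice(gene_pool, size=len(rhos), replace=False)
        rand_rhos = [
            r for g in draw
            if not math.isnan(r := spearman(mvec, gene_expr.row(g)))
        ]
        summaries.append(
            CorrelationSummary(
                m.mirna_id,
                float(np.median(rhos)),
                float(np.median(rand_rhos)) if rand_rhos else float("nan"),
                len(rhos),
            )
        )
    real = [s.median_rho_real for s in summaries]
    rand = [s.median_rho_random for s in summaries if not math.isnan(s.median_rho_random)]
    p = ks_one_sided(real, rand, "less") if real and rand else float("nan")
    return summaries, p, n_dropped


# ---------------------------------------------------------------------------
# TF time-course correlation
# ---------------------------------------------------------------------------

GROUP_NO_PROMOTER = "no_promoter"


def vlinc_tf_groups(
    annotations: Mapping[str, VlincAnnotation], factor: str
) -> dict[str, list[str]]:
    """The five comparison groups for one factor: no_promoter, LTR/nonLTR
    crossed with ChIPseq+/- status."""
    groups: dict[str, list[str]] = {
        GROUP_NO_PROMOTER: [],
        "LTR_chipseq_pos": [],
        "LTR_chipseq_neg": [],
        "nonLTR_chipseq_pos": [],
        "nonLTR_chipseq_neg": [],
    }
    for vid, ann in annotations.items():
        if ann.promoter_category == NO_PROMOTER:
            groups[GROUP_NO_PROMOTER].append(vid)
            continue
        prefix = "LTR" if ann.promoter_category == LTR else "nonLTR"
        suffix = "pos" if ann.tf_status.get(factor, False) else "neg"
        groups[f"{prefix}_chipseq_{suffix}"].append(vid)
    return groups


def tf_group_correlations(
    timecourse_expr: pd.DataFrame,
    tf_feature_ids: Mapping[str, str],
    groups_by_factor: Mapping[str, Mapping[str, Sequence[str]]],
) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """Spearman rho of each feature with each TF across time points,
    aggregated per group, plus all pairwise one-sided KS contrasts.

    *timecourse_expr* is features x ordered time points and must span at
    least 4 points for a rank correlation to mean anything.
    """
    if timecourse_expr.shape[1] < 4:
        raise ValueError("time course needs at least 4 points")
    dists: dict[tuple[str, str], np.ndarray] = {}
    for factor, tf_id in tf_feature_ids.items():
        tf_vec = timecourse_expr.loc[tf_id].to_numpy(dtype=float)
        for group, members in groups_by_factor[factor].items():
            rhos = [
                r
                for vid in members
                if vid in timecourse_expr.index
                and not math.isnan(
                    r := spearman(timecourse_expr.loc[vid].to_numpy(float), tf_vec)
                )
            ]
            dists[(factor, group)] = np.array(rhos)
    rows = []
    for factor in tf_feature_ids:
        group_names = list(groups_by_factor[factor])
        for ga in group_names:
            for gb in group_names:
                if ga == gb:
                    continue
                a, b = dists[(factor, ga)], dists[(factor, gb)]
                if len(a) == 0 or len(b) == 0:
                    continue
                rows.append(
                    {
                        "factor": factor,
                        "group_a": ga,
                        "group_b": gb,
                        "p_a_greater": ks_one_sided(a, b, "greater"),
                        "n_a": len(a),
                        "n_b": len(b),
                    }
                )
    return dists, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ChIP-seq flank enrichment
# ---------------------------------------------------------------------------

def sample_nonoverlapping_regions(
    chrom_sizes: Mapping[str, int],
    n_regions: int,
    region_len: int,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> list[GenomicInterval]:
    """Uniform non-overlapping regions of fixed length across the genome."""
    chroms = [c for c, size in chrom_sizes.items() if size >= region_len]
    if not chroms:
        raise ValueError("no chromosome can hold a region of this length")
    sizes = np.array([chrom_sizes[c] - region_len + 1 for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomicInterval] = []
    for _ in range(n_regions):
        for attempt in range(max_tries + 1):
            if attempt == max_tries:
                raise ValueError("genome too small for non-overlapping sampling")
            c = chroms[rng.choice(len(chroms), p=probs)]
            start = int(rng.integers(0, chrom_sizes[c] - region_len + 1))
            end = start + region_len
            if all(e <= start or end <= s for s, e in taken[c]):
                taken[c].append((start, end))
                out.append(GenomicInterval(c, start, end))
                break
    return out


def flank_peak_enrichment(
    flanks: Sequence[GenomicInterval],
    peaks_by_factor: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
    region_len: int = 10_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Empirical p that TF peaks concentrate in vlincRNA 5' flanks.

    Observed: peaks overlapping the flank set.  Null: the same count in
    len(flanks) freshly drawn non-overlapping random regions, repeated
    *n_perm* times.
    """
    rng = np.random.default_rng(seed)
    flanks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in flanks:
        flanks_by_chrom.setdefault(f.chrom, []).append(f)

    def count_in(regions: Sequence[GenomicInterval], peaks) -> int:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        return sum(
            1
            for p in peaks
            if any(p.overlaps(r) for r in by_chrom.get(p.chrom, []))
        )

    results = {}
    for factor, peaks in peaks_by_factor.items():
        observed = count_in(flanks, peaks)
        if not peaks:
            results[factor] = {"observed": 0, "p": 1.0}
            continue
        null = np.empty(n_perm)
        for i in range(n_perm):
            regions = sample_nonoverlapping_regions(
                chrom_sizes, len(flanks), region_len, rng
            )
            null[i] = count_in(regions, peaks)
        results[factor] = {
            "observed": observed,
            "null_mean": float(null.mean()),
            "p": empirical_perm_p(observed, null),
        }
    return results


def promoter_peak_signal(
    promoter_sets: Mapping[str, Sequence[GenomicInterval]],
    peak_tags_by_factor: Mapping[str, Sequence[GenomicInterval]],
) -> dict[tuple[str, str], np.ndarray]:
    """Per-promoter overlapping ChIP tag counts per (factor, category);
    promoters with zero tags for a factor are excluded from its distribution."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for factor, tags in peak_tags_by_factor.items():
        tags_by_chrom: dict[str, list[GenomicInterval]] = {}
        for t in tags:
            tags_by_chrom.setdefault(t.chrom, []).append(t)
        for category, proms in promoter_sets.items():
            counts = []
            for prom in proms:
                c = sum(
                    1 for t in tags_by_chrom.get(prom.chrom, []) if t.overlaps(prom)
                )
                if c > 0:
                    counts.append(c)
            out[(factor, category)] = np.array(counts, dtype=int)
    return out
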