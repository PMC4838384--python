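"""Sample-class statistics: RMECN, maximum-location counts, tag-mass
fractions, top-N enrichment and differentiation-trend tests.

vlincRNAs are highly cell-type specific, so class contrasts based on median
or mean expression wash out.  The working statistic is RMECN — the Ratio of
a feature's Maximum Expression across Cancer samples to its maximum across
Normal samples — compared between the LTR-promoter and nonLTR-promoter
classes.  Stem and immortalized samples are excluded from both maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import LTR, NONLTR, VlincAnnotation
from .intervals import GenomicInterval
from .quantify import ExpressionMatrix, TagSet
from .stats import (
    ContingencyTable2x2,
    empirical_perm_p,
    fisher_exact_one_sided,
    hypergeom_enrichment,
    mww_one_sided,
)

NORMAL, CANCER, STEM, IMMORTALIZED = "normal", "cancer", "stem", "immortalized"
SAMPLE_CLASSES = (NORMAL, CANCER, STEM, IMMORTALIZED)


@dataclass
class SampleTable:
    """Per-sample metadata: class label and optional time-course position."""

    table: pd.DataFrame  # index: sample_id; columns: class [, timecourse_id, time_index]

    def __post_init__(self) -> None:
        bad = set(self.table["class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes {sorted(bad)}")

    def ids_of(self, klass: str) -> list[str]:
        return list(self.table.index[self.table["class"] == klass])

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class RmecnResult:
    vlinc_id: str
    max_cancer: float
    max_normal: float
    rmecn: float  # NaN when max_normal == 0
    category: str


def _category_map(
    annotations: Mapping[str, VlincAnnotation]
) -> dict[str, str]:
    return {
        vid: ann.promoter_category
        for vid, ann in annotations.items()
        if ann.promoter_category in (LTR, NONLTR)
    }


def rmecn(
    expr: ExpressionMatrix,
    samples: SampleTable,
    annotations: Mapping[str, VlincAnnotation],
) -> tuple[list[RmecnResult], dict[str, float], int]:
    """Per-vlinc RMECN plus per-category medians.

    Only promoter-assigned vlincRNAs enter; ratios undefined because the
    normal maximum is zero are excluded from the medians and counted.
    """
    cancer_ids = [s for s in samples.ids_of(CANCER) if s in expr.values.columns]
    normal_ids = [s for s in samples.ids_of(NORMAL) if s in expr.values.columns]
    if not cancer_ids or not normal_ids:
        raise ValueError("need at least one cancer and one normal sample")
    cats = _category_map(annotations)
    results: list[RmecnResult] = []
    n_undefined = 0
    any_defined = False
    for vid, cat in cats.items():
        if vid not in expr.values.index:
            continue
        row = expr.values.loc[vid]
        mc = float(row[cancer_ids].max())
        mn = float(row[normal_ids].max())
        if mn == 0:
            n_undefined += 1
            results.append(RmecnResult(vid, mc, mn, float("nan"), cat))
        else:
            any_defined = True
            results.append(RmecnResult(vid, mc, mn, mc / mn, cat))
    if results and not any_defined:
        raise ValueError("every vlinc has zero normal maximum: degenerate design")
    medians = {}
    for cat in (LTR, NONLTR):
        vals = [r.rmecn for r in results if r.category == cat and not np.isnan(r.rmecn)]
        medians[cat] = float(np.median(vals)) if vals else float("nan")
    return results, medians, n_undefined


def _rmecn_ratio(
    M: np.ndarray, is_ltr: np.ndarray, cancer_mask: np.ndarray
) -> float:
    """median-RMECN(LTR) / median-RMECN(nonLTR) on a matrix restricted to
    cancer+normal columns; rows with zero normal max are dropped."""
    mc = M[:, cancer_mask].max(axis=1)
    mn = M[:, ~cancer_mask].max(axis=1)
    ok = mn > 0
    ratio = np.full(M.shape[0], np.nan)
    ratio[ok] = mc[ok] / mn[ok]
    med_ltr = np.nanmedian(ratio[is_ltr]) if np.any(is_ltr & ok) else np.nan
    med_non = np.nanmedian(ratio[~is_ltr]) if np.any(~is_ltr & ok) else np.nan
    return float(med_ltr / med_non)


def label_permutation_test(
    expr: ExpressionMatrix,
    samples: SampleTable,
    annotations: Mapping[str, VlincAnnotation],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Permute cancer/normal labels; statistic is the LTR/nonLTR ratio of
    median RMECN.  Returns (observed, empirical p, null draws)."""
    import warnings

    if n_perm < 100:
        warnings.warn(f"only {n_perm} permutations: p resolution is coarse")
    cancer_ids = [s for s in samples.ids_of(CANCER) if s in expr.values.columns]
    normal_ids = [s for s in samples.ids_of(NORMAL) if s in expr.values.columns]
    cols = cancer_ids + normal_ids
    cats = _category_map(annotations)
    vids = [v for v in cats if v in expr.values.index]
    M = expr.values.loc[vids, cols].to_numpy(dtype=float)
    is_ltr = np.array([cats[v] == LTR for v in vids])
    cancer_mask = np.array([True] * len(cancer_ids) + [False] * len(normal_ids))
    observed = _rmecn_ratio(M, is_ltr, cancer_mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _rmecn_ratio(M, is_ltr, rng.permutation(cancer_mask))
    return observed, empirical_perm_p(observed, null), null


def max_location_counts(
    expr: ExpressionMatrix,
    samples: SampleTable,
    annotations: Mapping[str, VlincAnnotation],
    exclude_stem_peaks: bool = False,
) -> tuple[ContingencyTable2x2, float]:
    """Category x (global maximum attained in a cancer sample) table + Fisher p.

    Ties are broken by first sample (column) position.  With
    *exclude_stem_peaks*, vlincRNAs peaking in a stem or immortalized
    sample are removed before tabulating.
    """
    import warnings

    klass = samples.table["class"]
    cats = _category_map(annotations)
    counts = {LTR: [0, 0], NONLTR: [0, 0]}  # [in cancer, not in cancer]
    all_const = True
    for vid, cat in cats.items():
        if vid not in expr.values.index:
            continue
        row = expr.values.loc[vid]
        if row.nunique() > 1:
            all_const = False
        peak_sample = row.index[int(np.argmax(row.to_numpy()))]
        peak_class = klass.get(peak_sample)
        if exclude_stem_peaks and peak_class in (STEM, IMMORTALIZED):
            continue
        counts[cat][0 if peak_class == CANCER else 1] += 1
    if all_const and cats:
        warnings.warn("expression matrix constant per vlinc: all maxima are ties")
    t = ContingencyTable2x2(
        counts[LTR][0], counts[LTR][1], counts[NONLTR][0], counts[NONLTR][1]
    )
    return t, fisher_exact_one_sided(t)


def mass_fractions(
    tagsets: Sequence[TagSet],
    sets: Mapping[str, Sequence[Sequence[GenomicInterval]]],
    all_vlinc_fragments: Sequence[Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-sample fraction of tags in each vlincRNA set, two normalizations.

    ``<set>_of_informative`` divides by the sample's informative-read total;
    ``<set>_of_vlinc_mass`` divides by the tags falling in all vlincRNA
    bodies (masked).  Sets are given as lists of per-vlinc fragment lists.
    """
    from .quantify import count_tags

    rows = {}
    for ts in tagsets:
        vlinc_mass = sum(count_tags(ts, frags) for frags in all_vlinc_fragments)
        row = {}
        for name, members in sets.items():
            in_set = sum(count_tags(ts, frags) for frags in members)
            row[f"{name}_of_informative"] = in_set / ts.informative_reads
            row[f"{name}_of_vlinc_mass"] = (
                in_set / vlinc_mass if vlinc_mass else 0.0
            )
        rows[ts.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def top_n_class_enrichment(
    fractions: pd.Series,
    samples: SampleTable,
    n: int = 100,
    klass: str = CANCER,
) -> dict:
    """Hypergeometric enrichment of *klass* among the top-*n* samples ranked
    by fraction (descending, ties broken by sample id)."""
    ranked = fractions.sort_index().sort_values(ascending=False, kind="stable")
    top = ranked.index[:n]
    members = set(samples.ids_of(klass))
    k = sum(1 for s in top if s in members)
    N = len(fractions)
    K = sum(1 for s in fractions.index if s in members)
    p, expected = hypergeom_enrichment(N, K, n, k)
    return {"p": p, "expected": expected, "observed": k, "n": n, "N": N, "K": K}


def class_fraction_tests(
    fractions: pd.Series, samples: SampleTable
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise one-sided MWW p-values (row class > column class) + medians."""
    present = [c for c in SAMPLE_CLASSES if samples.ids_of(c)]
    pmat = pd.DataFrame(np.nan, index=present, columns=present)
    medians = pd.Series(
        {
            c: float(fractions[[s for s in samples.ids_of(c) if s in fractions.index]].median())
            for c in present
        }
    )
    for c1 in present:
        for c2 in present:
            if c1 == c2:
                continue
            a = fractions[[s for s in samples.ids_of(c1) if s in fractions.index]]
            b = fractions[[s for s in samples.ids_of(c2) if s in fractions.index]]
            if len(a) and len(b):
                pmat.loc[c1, c2] = mww_one_sided(a, b, "greater")
    return pmat, medians


@dataclass(frozen=True)
class TrendResult:
    slope: float
    direction: str  # 'decrease' | 'increase' | 'flat'
    p: float | None  # None is the N/A sentinel for an increasing trend


def timecourse_trend(fractions: Sequence[float]) -> TrendResult:
    """Test for a decreasing linear trend of a fraction over time points.

    Ordinary least squares of fraction on time index; the overall regression
    F-test p, halved for the one-sided decreasing alternative, is reported
    when the slope is negative.  An increasing trend reports the N/A
    sentinel — the claim under test is specifically a decline.
    """
    from scipy import stats as sps

    y = np.asarray(fractions, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 time points")
    x = np.arange(y.size, dtype=float)
    if np.all(y == y[0]):
        # a constant series carries no evidence of decline
        return TrendResult(0.0, "flat", 1.0)
    res = sps.linregress(x, y)
    if res.slope < 0:
        return TrendResult(float(res.slope), "decrease", float(res.pvalue) / 2.0)
    return TrendResult(float(res.slope), "increase", None)
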