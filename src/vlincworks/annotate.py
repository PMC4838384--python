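"""Promoter, LTR, transcription-factor and distal status of features.

A feature's promoter set is every chromatin-state promoter element (any of
Active/Weak/Poised) overlapping a window around its transcription start
site: +/-5 kb for vlincRNAs, whose 5' ends are imprecisely annotated, and
+/-1 kb for genes.  A feature is 'LTR' when any assigned promoter overlaps
a long-terminal-repeat element — the retroviral-promoter class whose
cancer/pluripotency behaviour the downstream metrics interrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import (
    AnnotationBundle,
    GenomicInterval,
    PromoterElement,
    TranscriptModel,
)

VLINC_PROMOTER_WINDOW = 5_000
GENE_PROMOTER_WINDOW = 1_000
DISTAL_THRESHOLD = 50_000

LTR = "LTR"
NONLTR = "nonLTR"
NO_PROMOTER = "no_promoter"


@dataclass
class VlincAnnotation:
    vlinc_id: str
    promoter_category: str = NO_PROMOTER
    assigned_promoters: list[str] = field(default_factory=list)
    tf_status: dict[str, bool] = field(default_factory=dict)
    distal: bool = False

    @property
    def all_three_tfs(self) -> bool:
        return len(self.tf_status) >= 3 and all(self.tf_status.values())

    @property
    def any_tf(self) -> bool:
        return any(self.tf_status.values())


def assign_promoters(
    features: Sequence[TranscriptModel],
    promoters: Sequence[PromoterElement],
    ltr_repeats: Sequence[GenomicInterval],
    window_bp: int = VLINC_PROMOTER_WINDOW,
) -> dict[str, VlincAnnotation]:
    """Assign promoters within +/-window of each feature's TSS and call LTR status.

    Promoter state is not differentiated; category is LTR when any assigned
    promoter overlaps any LTR repeat on any strand.  Features without a
    resolved strand have no defined TSS and get no promoter.
    """
    out: dict[str, VlincAnnotation] = {}
    for feat in features:
        ann = VlincAnnotation(feat.id)
        out[feat.id] = ann
        if feat.strand == ".":
            continue
        tss = feat.body.five_prime()
        win = GenomicInterval(feat.chrom, max(0, tss - window_bp), tss + window_bp + 1)
        assigned = [p for p in promoters if p.interval.overlaps(win)]
        if not assigned:
            continue
        ann.assigned_promoters = [p.id for p in assigned]
        is_ltr = any(
            p.interval.overlaps(ltr) for p in assigned for ltr in ltr_repeats
        )
        ann.promoter_category = LTR if is_ltr else NONLTR
    return out


def tf_binding_status(
    annotations: Mapping[str, VlincAnnotation],
    promoters: Sequence[PromoterElement],
    tf_peaks: Mapping[str, Sequence[GenomicInterval]],
) -> None:
    """Set per-factor bound flags: any assigned promoter overlapping any peak."""
    prom_by_id = {p.id: p for p in promoters}
    for ann in annotations.values():
        proms = [prom_by_id[pid] for pid in ann.assigned_promoters]
        for factor, peaks in tf_peaks.items():
            ann.tf_status[factor] = any(
                p.interval.overlaps(peak) for p in proms for peak in peaks
            )


def distal_flag(
    vlincs: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    threshold: int = DISTAL_THRESHOLD,
) -> dict[str, bool]:
    """True for vlincRNAs with no gene body within *threshold* on either side.

    Either strand counts; a body-to-body gap of exactly the threshold is
    still distal ("separated by at least"). Overlapping gene bodies make a
    vlinc non-distal.
    """
    genes_by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, bool] = {}
    for v in vlincs:
        near = False
        for g in genes_by_chrom.get(v.chrom, []):
            if v.body.overlaps(g.body) or v.body.gap_to(g.body) < threshold:
                near = True
                break
        out[v.id] = not near
    return out


def annotate_vlincs(
    bundle: AnnotationBundle,
    window_bp: int = VLINC_PROMOTER_WINDOW,
    distal_threshold: int = DISTAL_THRESHOLD,
) -> dict[str, VlincAnnotation]:
    """Full annotation pass: promoters, LTR category, TF binding, distal flag."""
    anns = assign_promoters(
        bundle.vlincs, bundle.promoters, bundle.ltr_repeats, window_bp
    )
    tf_binding_status(anns, bundle.promoters, bundle.tf_peaks)
    for vid, flag in distal_flag(bundle.vlincs, bundle.genes, distal_threshold).items():
        anns[vid].distal = flag
    return anns
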