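"""Standalone designation and construction of vlincRNA genes.

A vlincRNA is a standalone transcript when, on each of its 5' and 3'
sides, either no same-strand gene lies within 50 kb, or every same-strand
gene within 50 kb is separated from it by an insulator element.  Standalone
vlincRNAs are then merged strand-specifically into non-redundant vlincRNA
genes.  Only same-strand genes can block standalone status: an antisense
neighbour is a different transcription unit by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import (
    GenomicInterval,
    TranscriptModel,
    separated_by_insulator,
    strand_specific_merge,
)

STANDALONE_THRESHOLD = 50_000

FAR_BOTH = "far_both_sides"
INSULATOR_BOTH = "insulator_both_sides"
FAR_ONE_INSULATOR_OTHER = "far_one_insulator_other"
NOT_STANDALONE = "not_standalone"


@dataclass(frozen=True)
class StandaloneCall:
    vlinc_id: str
    standalone: bool
    reason: str


@dataclass(frozen=True)
class VlincGene:
    gene_id: str
    interval: GenomicInterval
    member_vlinc_ids: tuple[str, ...]


def _side_clearance(
    vlinc: TranscriptModel,
    side_genes: Sequence[TranscriptModel],
    insulators: Sequence[GenomicInterval],
    threshold: int,
) -> str | None:
    """'far' if no same-strand gene within threshold on this side,
    'insulator' if all such genes are insulator-separated, None if blocked.

    A gene body-to-body gap of exactly the threshold still counts as within.
    """
    within = [g for g in side_genes if vlinc.body.gap_to(g.body) <= threshold]
    if not within:
        return "far"
    if all(separated_by_insulator(vlinc.body, g.body, insulators) for g in within):
        return "insulator"
    return None


def designate_standalone(
    vlinc: TranscriptModel,
    genes: Sequence[TranscriptModel],
    insulators: Sequence[GenomicInterval],
    threshold: int = STANDALONE_THRESHOLD,
) -> StandaloneCall:
    """Classify one vlincRNA by the 50-kb / insulator clearance rule.

    Genes are assigned to the vlinc's 5' or 3' side by their position
    relative to the body; short genes contained inside the body (allowed by
    the vlincRNA definition) block neither side.  Requires a resolved strand.
    """
    if vlinc.strand == ".":
        raise ValueError(f"vlinc {vlinc.id} has unresolved strand")
    left = [
        g
        for g in genes
        if g.chrom == vlinc.chrom and g.strand == vlinc.strand
        and g.body.end <= vlinc.body.start
    ]
    right = [
        g
        for g in genes
        if g.chrom == vlinc.chrom and g.strand == vlinc.strand
        and g.body.start >= vlinc.body.end
    ]
    if vlinc.strand == "+":
        five, three = left, right
    else:
        five, three = right, left

    c5 = _side_clearance(vlinc, five, insulators, threshold)
    c3 = _side_clearance(vlinc, three, insulators, threshold)
    if c5 is None or c3 is None:
        return StandaloneCall(vlinc.id, False, NOT_STANDALONE)
    if c5 == "far" and c3 == "far":
        reason = FAR_BOTH
    elif c5 == "insulator" and c3 == "insulator":
        reason = INSULATOR_BOTH
    else:
        reason = FAR_ONE_INSULATOR_OTHER
    return StandaloneCall(vlinc.id, True, reason)


def build_genes(standalone_vlincs: Sequence[TranscriptModel]) -> list[VlincGene]:
    """Merge standalone vlincRNAs strand-specifically into vlincRNA genes."""
    named = [
        GenomicInterval(v.chrom, v.body.start, v.body.end, v.strand, v.id)
        for v in standalone_vlincs
    ]
    merged = strand_specific_merge(named)
    return [
        VlincGene(f"vg_{i + 1:04d}", iv, tuple(members))
        for i, (iv, members) in enumerate(merged)
    ]


def designate_all(
    vlincs: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    insulators: Sequence[GenomicInterval],
    threshold: int = STANDALONE_THRESHOLD,
) -> tuple[list[StandaloneCall], list[VlincGene]]:
    """Designation plus gene building over a whole vlincRNA set."""
    calls = [
        designate_standalone(v, genes, insulators, threshold)
        for v in vlincs
        if v.strand != "."
    ]
    keep = {c.vlinc_id for c in calls if c.standalone}
    vgenes = build_genes([v for v in vlincs if v.id in keep])
    return calls, vgenes
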