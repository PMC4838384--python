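"""Genomic coordinate model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` on named chromosomes,
the native BED convention.  Strand is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
Every other module addresses the genome through the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open stranded span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Base-level overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def five_prime(self) -> int:
        """Position of the 5' base: start for '+', end - 1 for '-'.

        Unstranded intervals have no defined 5' end.
        """
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError(f"unstranded interval {self} has no 5' end")

    def three_prime(self) -> int:
        if self.strand == "+":
            return self.end - 1
        if self.strand == "-":
            return self.start
        raise ValueError(f"unstranded interval {self} has no 3' end")

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bases between nearest ends; 0 when overlapping or adjacent."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: a body span plus ordered non-overlapping exons.

    vlincRNAs are modelled as exonless transcripts — a single contiguous
    region of transcription.
    """

    id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.body.chrom or ex.strand != self.body.strand:
                raise ValueError(f"exon of {self.id} on wrong chrom/strand")
            if not self.body.contains(ex):
                raise ValueError(f"exon of {self.id} outside body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.id} unsorted or overlapping")
            prev_end = ex.end

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def chrom(self) -> str:
        return self.body.chrom


PROMOTER_STATES = ("Active", "Weak", "Poised")


@dataclass(frozen=True)
class PromoterElement:
    """A chromatin-state-derived promoter element (unstranded)."""

    interval: GenomicInterval
    state: str = "Active"
    source_cell_line: str = ""

    def __post_init__(self) -> None:
        if self.state not in PROMOTER_STATES:
            raise ValueError(f"bad promoter state {self.state!r}")

    @property
    def id(self) -> str:
        return self.interval.name


@dataclass
class AnnotationBundle:
    """All annotation tracks one analysis run consumes."""

    chrom_sizes: dict[str, int]
    genes: list[TranscriptModel] = field(default_factory=list)
    vlincs: list[TranscriptModel] = field(default_factory=list)
    promoters: list[PromoterElement] = field(default_factory=list)
    insulators: list[GenomicInterval] = field(default_factory=list)
    ltr_repeats: list[GenomicInterval] = field(default_factory=list)
    rrna_repeats: list[GenomicInterval] = field(default_factory=list)
    tf_peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    est_5p_ends: list[GenomicInterval] = field(default_factory=list)
    mirnas: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        """Check every interval's chromosome is declared and fits."""
        def check(iv: GenomicInterval, what: str) -> None:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"{what}: undeclared chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(f"{what}: {iv} beyond chromosome end {size}")

        for t in self.genes + self.vlincs:
            check(t.body, f"transcript {t.id}")
        for p in self.promoters:
            check(p.interval, f"promoter {p.id}")
        for label, track in (
            ("insulator", self.insulators),
            ("LTR", self.ltr_repeats),
            ("rRNA", self.rrna_repeats),
            ("EST5p", self.est_5p_ends),
            ("miRNA", self.mirnas),
        ):
            for iv in track:
                check(iv, label)
        for factor, peaks in self.tf_peaks.items():
            for iv in peaks:
                check(iv, f"peak {factor}")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def subtract_masks(
    target: GenomicInterval,
    masks: Sequence[GenomicInterval],
    strand_rule: str = "any_strand",
) -> tuple[list[GenomicInterval], int]:
    """Remove masked bases from *target*.

    Returns the sorted disjoint unmasked fragments and their total (residual)
    length.  ``strand_rule='same_strand'`` only applies masks whose strand
    equals the target's; ``'any_strand'`` applies all.  A fully masked target
    yields ``([], 0)``.
    """
    if strand_rule not in ("any_strand", "same_strand"):
        raise ValueError(f"bad strand_rule {strand_rule!r}")
    spans = []
    for m in masks:
        if m.chrom != target.chrom:
            continue
        if strand_rule == "same_strand" and m.strand != target.strand:
            continue
        s, e = max(m.start, target.start), min(m.end, target.end)
        if s < e:
            spans.append((s, e))
    spans.sort()
    fragments: list[GenomicInterval] = []
    cursor = target.start
    for s, e in spans:
        if s > cursor:
            fragments.append(replace(target, start=cursor, end=s))
        cursor = max(cursor, e)
    if cursor < target.end:
        fragments.append(replace(target, start=cursor, end=target.end))
    residual = sum(f.length for f in fragments)
    return fragments, residual


def separated_by_insulator(
    a: GenomicInterval,
    b: GenomicInterval,
    insulators: Sequence[GenomicInterval],
) -> bool:
    """True iff some insulator lies wholly within the gap between *a* and *b*.

    The gap is the open span between the facing ends of the two intervals.
    An insulator overlapping either interval does not count as separating;
    overlapping a/b have no gap and are never separated.  Insulator strand is
    ignored.
    """
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    gap_start = min(a.end, b.end)
    gap_end = max(a.start, b.start)
    if gap_start >= gap_end:
        return False
    return any(
        ins.chrom == a.chrom and gap_start <= ins.start and ins.end <= gap_end
        for ins in insulators
    )


def strand_specific_merge(
    intervals: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, list[str]]]:
    """Merge overlapping or touching intervals per (chrom, strand).

    Touching intervals merge (half-open adjacency is a zero-length gap).
    Returns ``(merged_interval, member_names)`` pairs sorted by position;
    member names preserve input order within each cluster.
    """
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[tuple[GenomicInterval, list[str]]] = []
    for (chrom, strand), ivs in groups.items():
        ivs = sorted(ivs, key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        members = [ivs[0].name]
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
                members.append(iv.name)
            else:
                out.append(
                    (GenomicInterval(chrom, cur_start, cur_end, strand), members)
                )
                cur_start, cur_end, members = iv.start, iv.end, [iv.name]
        out.append((GenomicInterval(chrom, cur_start, cur_end, strand), members))
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].strand))
    return out


def total_footprint(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct genomic bases covered, strand ignored."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total
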