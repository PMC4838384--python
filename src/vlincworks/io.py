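"""Readers and writers for the plain-text formats the pipeline exchanges.

BED intervals are interpreted as 0-based half-open, matching the internal
coordinate model, so no conversion happens on read or write.  GTF transcript
models are converted from 1-based inclusive on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import yaml

from .intervals import (
    AnnotationBundle,
    GenomicInterval,
    PromoterElement,
    TranscriptModel,
)


class FormatError(ValueError):
    """Malformed input line; message carries file and line number."""


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6; a missing strand column yields unstranded intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            if name == ".":
                name = ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_gtf_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Build transcript models from GTF exon records (1-based inclusive)."""
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GTF columns")
            if f[2] != "exon":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            tid = attrs.get("transcript_id", "").strip('"')
            if not tid:
                raise FormatError(f"{path}:{lineno}: missing transcript_id")
            exons.setdefault(tid, []).append(
                GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6], tid)
            )
    models = []
    for tid, exs in exons.items():
        exs.sort(key=lambda e: e.start)
        body = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand, tid
        )
        models.append(TranscriptModel(tid, body, tuple(exs)))
    return models


# ---------------------------------------------------------------------------
# Annotation bundle
# ---------------------------------------------------------------------------

_TRACK_FILES = {
    "genes": "genes.bed",
    "gene_exons": "gene_exons.bed",
    "vlincs": "vlincs.bed",
    "promoters": "promoters.bed",
    "insulators": "insulators.bed",
    "ltr_repeats": "ltr_repeats.bed",
    "rrna_repeats": "rrna_repeats.bed",
    "est_5p_ends": "est_5p_ends.bed",
    "mirnas": "mirnas.bed",
    "chrom_sizes": "chrom_sizes.tsv",
}


def write_annotation_bundle(bundle: AnnotationBundle, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    d = os.fspath(outdir)
    with open(os.path.join(d, "chrom_sizes.tsv"), "w") as fh:
        for name, size in bundle.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")
    write_bed([t.body for t in bundle.genes], os.path.join(d, "genes.bed"))
    write_bed(
        [ex for t in bundle.genes for ex in t.exons],
        os.path.join(d, "gene_exons.bed"),
    )
    write_bed([t.body for t in bundle.vlincs], os.path.join(d, "vlincs.bed"))
    # promoter state rides in the name as id|state|cell_line
    write_bed(
        [
            GenomicInterval(
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
                ".",
                f"{p.id}|{p.state}|{p.source_cell_line}",
            )
            for p in bundle.promoters
        ],
        os.path.join(d, "promoters.bed"),
    )
    write_bed(bundle.insulators, os.path.join(d, "insulators.bed"))
    write_bed(bundle.ltr_repeats, os.path.join(d, "ltr_repeats.bed"))
    write_bed(bundle.rrna_repeats, os.path.join(d, "rrna_repeats.bed"))
    write_bed(bundle.est_5p_ends, os.path.join(d, "est_5p_ends.bed"))
    write_bed(bundle.mirnas, os.path.join(d, "mirnas.bed"))
    for factor, peaks in bundle.tf_peaks.items():
        write_bed(peaks, os.path.join(d, f"tf_{factor}.bed"))


def read_annotation_bundle(
    config: str | os.PathLike | Mapping[str, str],
) -> AnnotationBundle:
    """Load a bundle from a directory, a YAML config of track paths, or a dict.

    A directory argument expects the canonical file names emitted by
    :func:`write_annotation_bundle`; a config maps track keys to paths and
    may add ``tf_peaks: {factor: path}``.
    """
    if isinstance(config, Mapping):
        paths = dict(config)
    elif os.path.isdir(config):
        d = os.fspath(config)
        paths = {
            key: os.path.join(d, fname)
            for key, fname in _TRACK_FILES.items()
            if os.path.exists(os.path.join(d, fname))
        }
        paths["tf_peaks"] = {
            fname[3:-4]: os.path.join(d, fname)
            for fname in sorted(os.listdir(d))
            if fname.startswith("tf_") and fname.endswith(".bed")
        }
    else:
        with open(config) as fh:
            paths = yaml.safe_load(fh)

    if "chrom_sizes" not in paths:
        raise KeyError("config missing required key 'chrom_sizes'")
    bundle = AnnotationBundle(chrom_sizes=read_chrom_sizes(paths["chrom_sizes"]))

    def bodies_to_transcripts(key: str, exon_key: str | None = None):
        bodies = read_bed(paths[key])
        exon_map: dict[str, list[GenomicInterval]] = {}
        if exon_key and exon_key in paths:
            for ex in read_bed(paths[exon_key]):
                exon_map.setdefault(ex.name, []).append(ex)
        models = []
        for b in bodies:
            exs = sorted(exon_map.get(b.name, []), key=lambda e: e.start)
            models.append(TranscriptModel(b.name, b, tuple(exs)))
        return models

    if "genes" in paths:
        bundle.genes = bodies_to_transcripts("genes", "gene_exons")
    if "vlincs" in paths:
        bundle.vlincs = bodies_to_transcripts("vlincs")
    if "promoters" in paths:
        proms = []
        for iv in read_bed(paths["promoters"]):
            pid, state, cell = (iv.name.split("|") + ["Active", ""])[:3]
            proms.append(
                PromoterElement(
                    GenomicInterval(iv.chrom, iv.start, iv.end, ".", pid),
                    state,
                    cell,
                )
            )
        bundle.promoters = proms
    for key in ("insulators", "ltr_repeats", "rrna_repeats", "est_5p_ends", "mirnas"):
        if key in paths:
            setattr(bundle, key, read_bed(paths[key]))
    for factor, path in (paths.get("tf_peaks") or {}).items():
        bundle.tf_peaks[factor] = read_bed(path)
    bundle.validate()
    return bundle


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
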