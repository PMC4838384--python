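"""Synthetic fixture world: annotation geometry, planted expression
structure and per-sample 5'-tag sets.

The generator emulates the statistical structure of a large capped-tag
compendium over a reduced genome: stranded vlincRNAs with a ~83 kb median
length, exon-bearing genes, chromatin-state promoters with an LTR subset,
insulators, TF peaks and miRNA loci.  Co-expression is planted through a
Gaussian copula with log-normal marginals, so a requested Spearman rho is
exact in expectation regardless of the marginal transform; class structure
is planted as a multiplicative boost of LTR-vlinc expression in cancer and
stem samples; a differentiation time course couples TF-bound LTR vlincs to
a declining TF trajectory; validated miRNA targets are negatively coupled
to their miRNA's surrogate feature.

Everything is deterministic under a fixed seed: one root seed fans out to
named substreams for annotation, expression and tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationBundle,
    GenomicInterval,
    PromoterElement,
    TranscriptModel,
)
from .classmetrics import CANCER, IMMORTALIZED, NORMAL, STEM, SampleTable
from .quantify import TagSet, effective_length
from .regulators import MirnaRecord

TF_FACTORS = ("OCT4", "SOX2", "NANOG")


@dataclass(frozen=True)
class PlanEntry:
    """One neighbour pair the generator must realize exactly."""

    configuration: str
    distance: int
    insulator: bool
    rho: float
    pair_type: str = "vlinc-gene"


def default_neighbor_plan() -> list[PlanEntry]:
    """Three distance regimes per configuration for vlinc-gene pairs, and a
    weaker gene-gene counterpart of each — the contrast the study design
    turns on."""
    configs = (
        "same_upstream",
        "same_downstream",
        "opposite_tail_to_tail",
        "opposite_head_to_head",
    )
    plan = []
    for c in configs:
        plan += [
            PlanEntry(c, 500, False, 0.55),
            PlanEntry(c, 2_000, True, 0.45),
            PlanEntry(c, 15_000, False, 0.30),
        ]
    for c in configs:
        plan += [
            PlanEntry(c, 500, False, 0.10, "gene-gene"),
            PlanEntry(c, 2_000, True, 0.10, "gene-gene"),
            PlanEntry(c, 15_000, False, 0.10, "gene-gene"),
        ]
    return plan


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 12_000_000
    n_genes: int = 300
    n_vlincs: int = 80
    vlinc_length_range: tuple[int, int] = (50_000, 116_000)  # median ~83 kb
    gene_length_range: tuple[int, int] = (5_000, 12_000)
    # sample counts scale the study's 399/332/92/10 class mix down to 60
    n_samples: dict = field(
        default_factory=lambda: {NORMAL: 29, CANCER: 24, STEM: 6, IMMORTALIZED: 1}
    )
    neighbor_plan: list = field(default_factory=default_neighbor_plan)
    promoter_fraction: float = 0.6
    ltr_fraction: float = 0.36  # of promoter-assigned vlincs, as in 611/1702
    tf_bound_fraction: float = 0.5  # of LTR vlincs; nonLTR use half this
    cancer_effect: float = 2.0
    timecourse_points: int = 16
    tf_coupling_rho: float = 0.8
    n_mirnas: int = 10
    targets_per_mirna: int = 8
    mirna_target_rho: float = -0.4
    tag_depth: int = 50_000
    background_tags: int = 5_000
    five_prime_peak_fraction: float = 0.5
    antisense_noise: float = 0.01
    # vlinc 5' ends are imprecisely annotated (repeat-rich, RNA-seq-derived
    # boundaries): this fraction of vlincs carries its true tag peak up to
    # tss_jitter_max bases downstream of the annotated start
    tss_jitter_fraction: float = 0.3
    tss_jitter_max: int = 20_000

    def __post_init__(self) -> None:
        if min(self.n_samples.values()) <= 0 or self.n_chrom <= 0:
            raise ValueError("all counts must be positive")
        for e in self.neighbor_plan:
            if abs(e.rho) > 1:
                raise ValueError(f"plan rho {e.rho} outside [-1, 1]")
        for p in (
            self.promoter_fraction,
            self.ltr_fraction,
            self.tf_bound_fraction,
            self.five_prime_peak_fraction,
            self.antisense_noise,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"fraction {p} outside [0, 1]")


@dataclass(frozen=True)
class PlantedPair:
    a_id: str
    b_id: str
    pair_type: str
    configuration: str
    distance: int
    insulator: bool
    rho: float


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    promoter_category: dict[str, str] = field(default_factory=dict)
    tf_bound: dict[str, set[str]] = field(default_factory=dict)
    mirna_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tf_feature_ids: dict[str, str] = field(default_factory=dict)
    timecourse_sample_ids: list[str] = field(default_factory=list)


@dataclass
class LatentExpression:
    matrix: pd.DataFrame  # features x samples, non-negative abundances
    truth: GroundTruth

    def __post_init__(self) -> None:
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative latent abundance")


# ---------------------------------------------------------------------------
# Annotation geometry
# ---------------------------------------------------------------------------

_SLOT_PITCH = 450_000
_INSULATOR_LEN = 100
_PROMOTER_HALF = 500


def _make_gene(
    gid: str, chrom: str, start: int, length: int, strand: str,
    rng: np.random.Generator,
) -> TranscriptModel:
    body = GenomicInterval(chrom, start, start + length, strand, gid)
    n_ex = int(rng.integers(2, 5))
    cuts = np.sort(rng.choice(np.arange(1, length // 100), n_ex * 2, replace=False)) * 100
    exons = tuple(
        GenomicInterval(chrom, start + int(cuts[2 * i]), start + int(cuts[2 * i + 1]),
                        strand, gid)
        for i in range(n_ex)
    )
    return TranscriptModel(gid, body, exons)


def generate_annotation(cfg: SimulationConfig) -> tuple[AnnotationBundle, GroundTruth]:
    """Lay out every track so each neighbour-plan entry is realized exactly.

    Planned pairs occupy widely separated slots on the first chromosome
    (one pair per slot, optional insulator wholly in the gap).  Remaining
    vlincRNAs are packed, gene-free, on the second chromosome — they are
    distal by construction — followed by the miRNA block and a cluster of
    unplanned genes.  Decoy short genes and rRNA repeats are dropped inside
    some vlinc bodies to exercise masking.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth = GroundTruth()
    chroms = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}
    bundle = AnnotationBundle(chrom_sizes=dict(chroms))
    if cfg.n_chrom < 2:
        raise ValueError("layout needs at least 2 chromosomes")
    n_slots_needed = len(cfg.neighbor_plan)
    if n_slots_needed * _SLOT_PITCH > cfg.chrom_length:
        raise ValueError(
            f"chromosome too short for {n_slots_needed} planned pairs"
        )

    vlinc_serial = iter(range(1, 10_000))
    gene_serial = iter(range(1, 10_000))

    def next_vlinc_id() -> str:
        return f"vlinc_{next(vlinc_serial):04d}"

    def next_gene_id() -> str:
        return f"gene_{next(gene_serial):04d}"

    def rand_len(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    # --- planned pairs on chr1 -------------------------------------------
    for i, entry in enumerate(cfg.neighbor_plan):
        slot = i * _SLOT_PITCH + 50_000
        chrom = "chr1"
        if entry.insulator and entry.distance < 3 * _INSULATOR_LEN:
            raise ValueError(
                f"plan entry {i}: gap {entry.distance} too narrow for an insulator"
            )
        glen = rand_len(*cfg.gene_length_range)
        if entry.pair_type == "vlinc-gene":
            alen = rand_len(*cfg.vlinc_length_range)
            a_id = next_vlinc_id()
        else:
            alen = rand_len(*cfg.gene_length_range)
            a_id = next_gene_id()
        # partner geometry: gene left of a for upstream/head-to-head,
        # right of a for downstream/tail-to-tail (a is '+')
        left_configs = ("same_upstream", "opposite_head_to_head")
        partner_left = entry.configuration in left_configs
        same = entry.configuration.startswith("same")
        b_strand = "+" if same else "-"
        a_start = slot + glen + entry.distance + 10_000
        if partner_left:
            b_start = a_start - entry.distance - glen
        else:
            b_start = a_start + alen + entry.distance
        b_id = next_gene_id()
        if entry.pair_type == "vlinc-gene":
            bundle.vlincs.append(
                TranscriptModel(
                    a_id, GenomicInterval(chrom, a_start, a_start + alen, "+", a_id)
                )
            )
        else:
            bundle.genes.append(_make_gene(a_id, chrom, a_start, alen, "+", rng))
        bundle.genes.append(_make_gene(b_id, chrom, b_start, glen, b_strand, rng))
        if entry.insulator:
            gap_lo = min(a_start + alen, b_start + glen)
            mid = gap_lo + entry.distance // 2
            bundle.insulators.append(
                GenomicInterval(chrom, mid - _INSULATOR_LEN // 2,
                                mid + _INSULATOR_LEN // 2)
            )
        # short contained genes (legal inside a vlinc body) in two planted
        # vlincs exercise exon masking without touching distal bookkeeping
        if entry.pair_type == "vlinc-gene" and i in (0, 6):
            bundle.genes.append(
                _make_gene(next_gene_id(), chrom, a_start + alen // 2, 4_000,
                           "+", rng)
            )
        truth.planted_pairs.append(
            PlantedPair(a_id, b_id, entry.pair_type, entry.configuration,
                        entry.distance, entry.insulator, entry.rho)
        )

    n_planted_vlincs = sum(
        1 for e in cfg.neighbor_plan if e.pair_type == "vlinc-gene"
    )

    # --- isolated (distal) vlincs packed on chr2 -------------------------
    cursor = 100_000
    chrom = "chr2"
    for i in range(cfg.n_vlincs - n_planted_vlincs):
        length = rand_len(*cfg.vlinc_length_range)
        if cursor + length > cfg.chrom_length - 100_000:
            raise ValueError("chr2 too short for the requested vlinc count")
        vid = next_vlinc_id()
        strand = "+" if i % 2 == 0 else "-"
        body = GenomicInterval(chrom, cursor, cursor + length, strand, vid)
        bundle.vlincs.append(TranscriptModel(vid, body))
        # masking decoys that leave distal status untouched
        if i % 4 == 3:
            r0 = cursor + length // 2
            bundle.rrna_repeats.append(GenomicInterval(chrom, r0, r0 + 500))
        if i % 5 == 2:
            e0 = cursor + 2 * length // 3
            bundle.est_5p_ends.append(GenomicInterval(chrom, e0, e0 + 1, strand))
        if i % 6 == 4:  # stray insulators inside the pack gaps
            bundle.insulators.append(
                GenomicInterval(chrom, cursor + length + 4_000,
                                cursor + length + 4_000 + _INSULATOR_LEN)
            )
        cursor += length + 12_000

    # --- miRNA block ------------------------------------------------------
    cursor += 80_000
    for i in range(cfg.n_mirnas):
        mid = f"mir_{i + 1:03d}"
        bundle.mirnas.append(GenomicInterval(chrom, cursor, cursor + 80, "+", mid))
        cursor += 20_000

    # --- unplanned gene cluster ------------------------------------------
    cursor += 80_000
    n_cluster = cfg.n_genes - len(bundle.genes)
    for _ in range(max(0, n_cluster)):
        length = rand_len(*cfg.gene_length_range)
        if cursor + length > cfg.chrom_length - 50_000:
            raise ValueError("chr2 too short for the requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        bundle.genes.append(_make_gene(next_gene_id(), chrom, cursor, length,
                                       strand, rng))
        cursor += length + int(rng.integers(4_000, 8_000))

    # --- promoters, LTRs, TF peaks ---------------------------------------
    # promoters are drawn from the isolated vlincs only: the planted
    # neighbour pairs must keep their copula correlation untouched by the
    # class-dependent LTR boost, so no feature sits in two planted blocks
    all_vids = [v.id for v in bundle.vlincs]
    planted_vids = {
        p.a_id for p in truth.planted_pairs if p.pair_type == "vlinc-gene"
    }
    isolated_vids = [vid for vid in all_vids if vid not in planted_vids]
    n_prom = min(
        int(round(cfg.promoter_fraction * len(all_vids))), len(isolated_vids)
    )
    prom_vids = list(rng.choice(isolated_vids, size=n_prom, replace=False))
    n_ltr = int(round(cfg.ltr_fraction * n_prom))
    ltr_vids = set(prom_vids[:n_ltr])
    vlinc_by_id = {v.id: v for v in bundle.vlincs}
    states = ("Active", "Weak", "Poised")
    for j, vid in enumerate(prom_vids):
        v = vlinc_by_id[vid]
        tss = v.body.five_prime()
        lo = max(0, tss - _PROMOTER_HALF)
        prom = PromoterElement(
            GenomicInterval(v.chrom, lo, tss + _PROMOTER_HALF, ".", f"prom_{vid}"),
            states[j % 3],
            "simulated",
        )
        bundle.promoters.append(prom)
        truth.promoter_category[vid] = "LTR" if vid in ltr_vids else "nonLTR"
        if vid in ltr_vids:
            bundle.ltr_repeats.append(
                GenomicInterval(v.chrom, lo, lo + 400, ".", f"ltr_{vid}")
            )
    for vid in set(all_vids) - set(prom_vids):
        truth.promoter_category[vid] = "no_promoter"

    ltr_list = sorted(ltr_vids)
    non_list = sorted(set(prom_vids) - ltr_vids)
    n_tf_ltr = int(round(cfg.tf_bound_fraction * len(ltr_list)))
    n_tf_non = int(round(cfg.tf_bound_fraction / 2 * len(non_list)))
    bound = set(ltr_list[:n_tf_ltr]) | set(non_list[:n_tf_non])
    for factor in TF_FACTORS:
        bundle.tf_peaks[factor] = []
        truth.tf_bound[factor] = set(bound)
        for vid in sorted(bound):
            v = vlinc_by_id[vid]
            tss = v.body.five_prime()
            lo = max(0, tss - 200)
            bundle.tf_peaks[factor].append(
                GenomicInterval(v.chrom, lo, lo + 300, ".", f"{factor}_{vid}")
            )

    # TF transcripts live in the gene cluster (never planted as neighbours)
    cluster_gene_ids = [g.id for g in bundle.genes if g.chrom == "chr2"
                        and g.body.length > 4_500]
    for factor, gid in zip(TF_FACTORS, cluster_gene_ids[:3]):
        truth.tf_feature_ids[factor] = gid

    # miRNA validated targets drawn from cluster genes not otherwise planted
    target_pool = [g for g in cluster_gene_ids[3:]]
    need = cfg.n_mirnas * cfg.targets_per_mirna
    if len(target_pool) < need:
        raise ValueError("not enough cluster genes for the miRNA target plan")
    for i, m in enumerate(bundle.mirnas):
        chunk = target_pool[i * cfg.targets_per_mirna:(i + 1) * cfg.targets_per_mirna]
        truth.mirna_targets[m.name] = tuple(chunk)

    bundle.validate()
    return bundle, truth


# ---------------------------------------------------------------------------
# Latent expression
# ---------------------------------------------------------------------------

def _copula_r(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula that yields Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], SampleTable]:
    prefix = {NORMAL: "n", CANCER: "c", STEM: "s", IMMORTALIZED: "i"}
    main = []
    rows = {}
    for klass in (NORMAL, CANCER, STEM, IMMORTALIZED):
        for i in range(cfg.n_samples[klass]):
            sid = f"{prefix[klass]}{i + 1:03d}"
            main.append(sid)
            rows[sid] = {"class": klass, "timecourse_id": "", "time_index": -1}
    tc = []
    for t in range(cfg.timecourse_points):
        sid = f"tc{t:02d}"
        tc.append(sid)
        rows[sid] = {"class": STEM, "timecourse_id": "tc1", "time_index": t}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return main, tc, SampleTable(table)


def generate_expression(
    cfg: SimulationConfig, bundle: AnnotationBundle, truth: GroundTruth
) -> tuple[LatentExpression, SampleTable]:
    """Latent non-negative abundances with every planted structure.

    Log-normal marginals over a Gaussian copula; each planted block is
    realized by conditional construction, which is always a valid
    correlation structure provided no feature sits in two blocks — a
    feature claimed twice raises with the offending block named.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    main, tc, samples = sample_ids(cfg)
    cols = main + tc
    truth.timecourse_sample_ids = list(tc)
    feature_ids = (
        [g.id for g in bundle.genes]
        + [v.id for v in bundle.vlincs]
        + [m.name for m in bundle.mirnas]
    )
    idx = {f: i for i, f in enumerate(feature_ids)}
    n_f, n_s = len(feature_ids), len(cols)
    Z = rng.standard_normal((n_f, n_s))

    claimed: dict[str, str] = {}

    def claim(fid: str, block: str) -> None:
        if fid in claimed:
            raise ValueError(
                f"feature {fid} in two planted blocks: {claimed[fid]} and {block}"
            )
        claimed[fid] = block

    for pair in truth.planted_pairs:
        block = f"pair({pair.a_id},{pair.b_id})"
        claim(pair.a_id, block)
        claim(pair.b_id, block)
        r = _copula_r(pair.rho)
        eps = rng.standard_normal(n_s)
        Z[idx[pair.b_id]] = r * Z[idx[pair.a_id]] + math.sqrt(1 - r * r) * eps

    for mid, targets in truth.mirna_targets.items():
        claim(mid, f"mirna({mid})")
        r = _copula_r(cfg.mirna_target_rho)
        for t in targets:
            claim(t, f"mirna({mid})")
            eps = rng.standard_normal(n_s)
            Z[idx[t]] = r * Z[idx[mid]] + math.sqrt(1 - r * r) * eps

    # time course: declining TF trajectories, coupled TF-bound LTR vlincs
    tc_slice = slice(len(main), n_s)
    n_tc = len(tc)
    trend = np.linspace(1.5, -1.5, n_tc)
    bound_any = set.union(*truth.tf_bound.values()) if truth.tf_bound else set()
    coupled = sorted(
        vid for vid in bound_any if truth.promoter_category.get(vid) == "LTR"
    )
    tf_gene_ids = list(truth.tf_feature_ids.values())
    for gid in tf_gene_ids:
        Z[idx[gid], tc_slice] = trend + 0.25 * rng.standard_normal(n_tc)
    if tf_gene_ids:
        ref = Z[idx[tf_gene_ids[0]], tc_slice]
        ref_std = (ref - ref.mean()) / ref.std()
        r = _copula_r(cfg.tf_coupling_rho)
        for vid in coupled:
            eps = rng.standard_normal(n_tc)
            Z[idx[vid], tc_slice] = r * ref_std + math.sqrt(1 - r * r) * eps

    mu = rng.normal(0.0, 0.8, size=n_f)
    A = np.exp(mu[:, None] + Z)

    # cancer/stem boost for LTR vlincs (multiplicative on the maxima scale)
    boost_cols = np.array(
        [samples.table.loc[s, "class"] in (CANCER, STEM) for s in cols]
    )
    for vid, cat in truth.promoter_category.items():
        if cat == "LTR":
            A[idx[vid], boost_cols] *= cfg.cancer_effect

    matrix = pd.DataFrame(A, index=feature_ids, columns=cols)
    return LatentExpression(matrix, truth), samples


# ---------------------------------------------------------------------------
# Tag emission
# ---------------------------------------------------------------------------

def _oriented_positions(
    fragments: Sequence[GenomicInterval], strand: str, offsets: np.ndarray
) -> np.ndarray:
    """Map 5'->3' offsets along concatenated fragments to genomic positions."""
    frags = sorted(fragments, key=lambda f: f.start)
    if strand == "-":
        frags = frags[::-1]
    lengths = np.array([f.length for f in frags])
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    which = np.searchsorted(np.cumsum(lengths), offsets, side="right")
    pos = np.empty_like(offsets)
    for i, f in enumerate(frags):
        sel = which == i
        local = offsets[sel] - starts[i]
        if strand == "+":
            pos[sel] = f.start + local
        else:
            pos[sel] = f.end - 1 - local
    return pos


def _feature_tag_positions(
    fragments: Sequence[GenomicInterval],
    strand: str,
    n: int,
    peak_fraction: float,
    rng: np.random.Generator,
    peak_offset: int = 0,
) -> np.ndarray:
    total = sum(f.length for f in fragments)
    n_peak = rng.binomial(n, peak_fraction)
    peak_offset = min(peak_offset, max(0, total - 500))
    peak_span = min(500, total - peak_offset)
    off_peak = peak_offset + rng.integers(0, peak_span, size=n_peak)
    u = rng.random(n - n_peak)
    off_body = np.floor(total * (1.0 - np.sqrt(1.0 - u))).astype(np.int64)
    off_body = np.minimum(off_body, total - 1)
    offsets = np.concatenate([off_peak, off_body])
    return _oriented_positions(fragments, strand, offsets)


def generate_tags(
    cfg: SimulationConfig,
    bundle: AnnotationBundle,
    latent: LatentExpression,
) -> list[TagSet]:
    """Per-sample tag sets: Poisson counts scaled to the configured depth,
    5'-peaked positions over unmasked bodies, antisense noise and uniform
    background.  The informative total is every emitted tag."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    # per-feature emission geometry
    geom: dict[str, tuple[list[GenomicInterval], str]] = {}
    for g in bundle.genes:
        geom[g.id] = (list(g.exons), g.strand)
    for v in bundle.vlincs:
        frags, length = effective_length(v, bundle)
        if length > 0:
            geom[v.id] = (frags, v.strand)
    for m in bundle.mirnas:
        geom[m.name] = ([m], m.strand)

    # per-vlinc annotation-offset of the true 5' peak, fixed across samples
    peak_offset_of = {fid: 0 for fid in geom}
    vlinc_ids = [v.id for v in bundle.vlincs]
    n_jit = int(round(cfg.tss_jitter_fraction * len(vlinc_ids)))
    for vid in rng.choice(vlinc_ids, size=n_jit, replace=False):
        peak_offset_of[vid] = int(rng.integers(6_000, cfg.tss_jitter_max + 1))

    chrom_names = list(bundle.chrom_sizes)
    chrom_sizes = np.array([bundle.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_probs = chrom_sizes / chrom_sizes.sum()

    tagsets = []
    M = latent.matrix
    M_np = M.to_numpy()
    row_of = {fid: i for i, fid in enumerate(M.index)}
    col_sums = M_np.sum(axis=0)
    for j, sid in enumerate(M.columns):
        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        strands: list[np.ndarray] = []
        scale = cfg.tag_depth / float(col_sums[j])
        for fid, (frags, strand) in geom.items():
            lam = float(M_np[row_of[fid], j]) * scale
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            pos = _feature_tag_positions(
                frags, strand, n, cfg.five_prime_peak_fraction, rng,
                peak_offset_of.get(fid, 0),
            )
            st = np.full(n, strand, dtype=object)
            flip = rng.random(n) < cfg.antisense_noise
            st[flip] = np.where(st[flip] == "+", "-", "+")
            chroms.append(np.full(n, frags[0].chrom, dtype=object))
            positions.append(pos)
            strands.append(st)
        n_bg = int(rng.poisson(cfg.background_tags))
        if n_bg:
            ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_probs)
            bg_pos = (rng.random(n_bg) * chrom_sizes[ci]).astype(np.int64)
            chroms.append(np.array([chrom_names[i] for i in ci], dtype=object))
            positions.append(bg_pos)
            strands.append(
                np.where(rng.random(n_bg) < 0.5, "+", "-").astype(object)
            )
        tags = pd.DataFrame(
            {
                "chrom": np.concatenate(chroms) if chroms else np.array([], object),
                "pos": np.concatenate(positions).astype(np.int64)
                if positions else np.array([], np.int64),
                "strand": np.concatenate(strands) if strands else np.array([], object),
            }
        )
        tags["count"] = 1
        tagsets.append(TagSet(sid, tags, informative_reads=int(len(tags))))
    return tagsets


# ---------------------------------------------------------------------------
# One-call world
# ---------------------------------------------------------------------------

@dataclass
class SimulatedWorld:
    cfg: SimulationConfig
    bundle: AnnotationBundle
    truth: GroundTruth
    latent: LatentExpression
    samples: SampleTable
    tagsets: list[TagSet]

    @property
    def mirna_records(self) -> list[MirnaRecord]:
        return [
            MirnaRecord(m.name, m, self.truth.mirna_targets[m.name])
            for m in self.bundle.mirnas
        ]


def simulate_world(cfg: SimulationConfig | None = None) -> SimulatedWorld:
    cfg = cfg or SimulationConfig()
    bundle, truth = generate_annotation(cfg)
    latent, samples = generate_expression(cfg, bundle, truth)
    tagsets = generate_tags(cfg, bundle, latent)
    return SimulatedWorld(cfg, bundle, truth, latent, samples, tagsets)
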