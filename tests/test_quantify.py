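"""Tag counting, masking-aware effective lengths, the two RPKM scalings,
strand calling and 5'-end density profiles."""

import numpy as np
import pandas as pd
import pytest

from vlincworks.intervals import AnnotationBundle, GenomicInterval, TranscriptModel
from vlincworks.quantify import (
    TagSet,
    build_expression_matrix,
    call_strand,
    count_tags,
    effective_length,
    flank_intervals,
    rnaseq_count,
    rpkm,
    tss_density_profile,
)
from vlincworks.stats import spearman

from .oracles import count_tags_double_loop


def make_tagset(rows, informative=None, sample="s1"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return TagSet(sample, df, informative or int(df["count"].sum()))


def gi(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


class TestCountTags:
    def test_tag_on_start_border_counted(self):
        ts = make_tagset([("chr1", 100, "+", 1)])
        assert count_tags(ts, [gi(100, 200)]) == 1

    def test_tag_at_exclusive_end_not_counted(self):
        ts = make_tagset([("chr1", 200, "+", 1)])
        assert count_tags(ts, [gi(100, 200)]) == 0

    def test_opposite_strand_not_counted(self):
        ts = make_tagset([("chr1", 150, "-", 1)])
        assert count_tags(ts, [gi(100, 200, "+")]) == 0

    def test_multiplicities_summed(self):
        ts = make_tagset([("chr1", 150, "+", 3), ("chr1", 160, "+", 2)])
        assert count_tags(ts, [gi(100, 200)]) == 5

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            rows = [
                (
                    rng.choice(["chr1", "chr2"]),
                    int(rng.integers(0, 1_000)),
                    rng.choice(["+", "-"]),
                    int(rng.integers(1, 4)),
                )
                for _ in range(1000)
            ]
            frags = [
                gi(s := int(rng.integers(0, 900)), s + int(rng.integers(1, 100)),
                   rng.choice(["+", "-"]), chrom=rng.choice(["chr1", "chr2"]))
                for _ in range(5)
            ]
            # make fragments disjoint per chrom/strand by keeping first-come spans
            kept = []
            for f in frags:
                if not any(
                    f.chrom == k.chrom and f.strand == k.strand and f.overlaps(k)
                    for k in kept
                ):
                    kept.append(f)
            ts = make_tagset(rows)
            assert count_tags(ts, kept) == count_tags_double_loop(rows, kept)

    def test_channel_split_invariance(self, rng):
        rows = [
            ("chr1", int(rng.integers(0, 1_000)), "+", 1) for _ in range(400)
        ]
        frags = [gi(100, 700)]
        whole = count_tags(make_tagset(rows), frags)
        split = count_tags(make_tagset(rows[:150]), frags) + count_tags(
            make_tagset(rows[150:]), frags
        )
        assert whole == split


class TestEffectiveLength:
    def _bundle(self, genes=(), rrna=(), ests=(), promoters=()):
        return AnnotationBundle(
            chrom_sizes={"chr1": 10_000_000},
            genes=list(genes),
            rrna_repeats=list(rrna),
            est_5p_ends=list(ests),
            promoters=list(promoters),
        )

    def test_exon_and_rrna_masks_reduce_length(self):
        vlinc = TranscriptModel("v", gi(0, 100_000))
        gene = TranscriptModel(
            "g", gi(10_000, 20_000, "-"), (gi(10_000, 15_000, "-"),)
        )
        bundle = self._bundle(genes=[gene], rrna=[gi(50_000, 51_000, ".")])
        _, length = effective_length(vlinc, bundle)
        assert length == 94_000

    def test_gene_exonic_length(self):
        g = TranscriptModel(
            "g", gi(0, 2_000), (gi(0, 200), gi(300, 600), gi(1_000, 1_500))
        )
        assert g.exonic_length == 1000

    def test_est_masks_are_strand_specific(self):
        vlinc = TranscriptModel("v", gi(0, 100_000, "+"))
        same = gi(50_000, 50_001, "+")
        anti = gi(70_000, 70_001, "-")
        bundle = self._bundle(ests=[same, anti])
        _, length = effective_length(vlinc, bundle, extra_masks="est_5p")
        # only the same-strand EST window (+/-1 kb around a 1 bp end) is cut
        assert length == 100_000 - 2_001

    def test_random_masks_match_per_base_oracle(self, rng):
        from .oracles import masked_residual_per_base

        for _ in range(30):
            vlinc = TranscriptModel("v", gi(0, 50_000, "+"))
            exons = [
                gi(s := int(rng.integers(0, 49_000)), s + int(rng.integers(1, 900)),
                   rng.choice(["+", "-"]))
                for _ in range(10)
            ]
            genes = []
            for k in range(0, 10, 2):
                pair = sorted(exons[k:k + 2], key=lambda e: e.start)
                if pair[0].end > pair[1].start:
                    pair = pair[:1]
                body = gi(pair[0].start, pair[-1].end, pair[0].strand)
                ex = tuple(
                    GenomicInterval(e.chrom, e.start, e.end, pair[0].strand)
                    for e in pair
                )
                genes.append(TranscriptModel(f"g{k}", body, ex))
            bundle = self._bundle(genes=genes)
            _, length = effective_length(vlinc, bundle)
            all_exons = [e for g in genes for e in g.exons]
            assert length == masked_residual_per_base(
                vlinc.body, all_exons, "any_strand"
            )


class TestRpkm:
    def test_gene_formula_instantiation(self):
        assert rpkm(100, 10**7, 1000, "gene") == pytest.approx(10.0)

    def test_vlinc_scale_is_hundredfold(self):
        assert rpkm(100, 10**7, 1000, "vlinc") == pytest.approx(1000.0)

    def test_zero_raw_is_zero(self):
        assert rpkm(0, 10**6, 500, "gene") == 0.0

    def test_linearity_and_inverse_scaling(self):
        base = rpkm(50, 10**6, 2000, "vlinc")
        assert rpkm(100, 10**6, 2000, "vlinc") == pytest.approx(2 * base)
        assert rpkm(50, 2 * 10**6, 2000, "vlinc") == pytest.approx(base / 2)
        assert rpkm(50, 10**6, 4000, "vlinc") == pytest.approx(base / 2)

    def test_invalid_denominators_raise(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100, "gene")
        with pytest.raises(ValueError):
            rpkm(1, 100, 0, "gene")


class TestRnaseqCount:
    def test_read_fully_inside_counts_one(self):
        assert rnaseq_count([gi(120, 150)], [gi(100, 200)]) == 1.0

    def test_border_crossing_counts_half(self):
        assert rnaseq_count([gi(80, 120)], [gi(100, 200)]) == 0.5

    def test_wrong_strand_counts_zero(self):
        assert rnaseq_count([gi(120, 150, "-")], [gi(100, 200, "+")]) == 0.0

    def test_random_reads_match_oracle(self, rng):
        for _ in range(30):
            frag = gi(200, 800)
            reads = [
                gi(s := int(rng.integers(0, 950)), s + 50, rng.choice(["+", "-"]))
                for _ in range(100)
            ]
            expect = sum(
                (1.0 if frag.contains(r) else 0.5)
                if r.strand == "+" and r.overlaps(frag)
                else 0.0
                for r in reads
            )
            assert rnaseq_count(reads, [frag]) == expect


class TestCallStrand:
    def test_majority_wins(self):
        ts = make_tagset(
            [("chr1", 100, "+", 10), ("chr1", 110, "-", 3)]
        )
        v = TranscriptModel("v", gi(0, 1_000, "."))
        assert call_strand(v, ts) == "+"

    def test_tie_is_unresolved(self):
        ts = make_tagset([("chr1", 100, "+", 2), ("chr1", 110, "-", 2)])
        v = TranscriptModel("v", gi(0, 1_000, "."))
        assert call_strand(v, ts) == "."
        empty = make_tagset([("chr2", 5, "+", 1)])
        assert call_strand(v, empty) == "."

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            rows = [
                ("chr1", int(rng.integers(0, 2_000)), rng.choice(["+", "-"]), 1)
                for _ in range(50)
            ]
            v = TranscriptModel("v", gi(500, 1_500, "."))
            plus = sum(1 for _, p, s, _ in rows if s == "+" and 500 <= p < 1500)
            minus = sum(1 for _, p, s, _ in rows if s == "-" and 500 <= p < 1500)
            expect = "+" if plus > minus else "-" if minus > plus else "."
            assert call_strand(v, make_tagset(rows)) == expect


class TestTssDensityProfile:
    def test_all_tags_at_tss_fill_first_downstream_bin(self):
        v = TranscriptModel("v", gi(50_000, 150_000, "+"))
        ts = make_tagset([("chr1", 50_000, "+", 7)])
        profile = tss_density_profile([v], [ts])
        assert profile[10] == 7 and profile.sum() == 7

    def test_minus_strand_reported_five_to_three(self):
        v = TranscriptModel("v", gi(50_000, 150_000, "-"))
        # 600 bp upstream of the 5' end (which is the right boundary)
        ts = make_tagset([("chr1", 150_000 - 1 + 600, "-", 1)])
        profile = tss_density_profile([v], [ts])
        assert profile[8] == 1  # upstream flank, second bin out

    def test_no_tags_zero_vector(self):
        v = TranscriptModel("v", gi(50_000, 150_000, "+"))
        assert tss_density_profile([v], [make_tagset([("chr2", 1, "+", 1)])]).sum() == 0

    def test_outlier_exclusion(self):
        v = TranscriptModel("v", gi(50_000, 150_000, "+"))
        ts = make_tagset([("chr1", 50_000, "+", 100)])
        assert tss_density_profile([v], [ts], exclude=["v"]).sum() == 0

    def test_random_placement_matches_binning_oracle(self, rng):
        v = TranscriptModel("v", gi(100_000, 200_000, "-"))
        rows = [
            ("chr1", int(rng.integers(194_000, 206_000)), "-", 1)
            for _ in range(300)
        ]
        profile = tss_density_profile([v], [make_tagset(rows)])
        expect = np.zeros(20, dtype=int)
        tss = 200_000 - 1
        for _, pos, _, _ in rows:
            o = tss - pos
            if -5_000 <= o < 5_000:
                expect[(o + 5_000) // 500] += 1
        assert (profile == expect).all()


class TestExpressionMatrix:
    def test_internal_beats_flank_against_rnaseq(self, world, rng):
        """Body-wide tag counting tracks an RNA-seq-style measurement better
        than the classical 5'-flank window for vlincRNAs."""
        internal = build_expression_matrix(world.tagsets[:1], world.bundle, "internal")
        flank = build_expression_matrix(world.tagsets[:1], world.bundle, "flank")
        lat = world.latent.matrix[world.tagsets[0].sample_id]
        # RNA-seq-style reads for every vlinc in one sample
        scale = 2_000 / lat.sum()
        rna = {}
        for v in world.bundle.vlincs:
            n = rng.poisson(lat[v.id] * scale * len(lat))
            starts = rng.integers(v.body.start, v.body.end - 50, size=int(n))
            reads = [GenomicInterval(v.chrom, int(s), int(s) + 50, v.strand)
                     for s in starts]
            rna[v.id] = rnaseq_count(reads, [v.body])
        common = [v.id for v in world.bundle.vlincs
                  if v.id in internal.values.index and v.id in flank.values.index]
        rna_v = [rna[i] for i in common]
        rho_int = spearman(internal.values.loc[common].iloc[:, 0], rna_v)
        rho_fl = spearman(flank.values.loc[common].iloc[:, 0], rna_v)
        assert rho_int > rho_fl

    def test_matrix_cells_match_direct_recomputation(self, world):
        expr = build_expression_matrix(world.tagsets[:2], world.bundle, "internal")
        ts = world.tagsets[0]
        checked = 0
        for v in world.bundle.vlincs[:10]:
            frags, length = effective_length(v, world.bundle)
            if length == 0:
                continue
            raw = count_tags(ts, frags)
            expect = raw / (ts.informative_reads * length) * 1e11
            assert expr.values.loc[v.id, ts.sample_id] == pytest.approx(
                expect, rel=1e-9
            )
            checked += 1
        assert checked >= 5
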