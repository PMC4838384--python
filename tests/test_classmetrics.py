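"""RMECN, maximum-location counts, tag-mass fractions, top-N class
enrichment and time-course trends."""

import numpy as np
import pandas as pd
import pytest

from vlincworks.annotate import LTR, NONLTR, VlincAnnotation
from vlincworks.classmetrics import (
    SampleTable,
    class_fraction_tests,
    label_permutation_test,
    mass_fractions,
    max_location_counts,
    rmecn,
    timecourse_trend,
    top_n_class_enrichment,
)
from vlincworks.intervals import GenomicInterval
from vlincworks.quantify import ExpressionMatrix, TagSet


def make_samples(n_cancer=4, n_normal=4, n_stem=0):
    rows = {}
    for i in range(n_cancer):
        rows[f"c{i}"] = {"class": "cancer"}
    for i in range(n_normal):
        rows[f"n{i}"] = {"class": "normal"}
    for i in range(n_stem):
        rows[f"s{i}"] = {"class": "stem"}
    t = pd.DataFrame.from_dict(rows, orient="index")
    t.index.name = "sample_id"
    return SampleTable(t)


def make_expr(data: dict) -> ExpressionMatrix:
    df = pd.DataFrame(data).T
    return ExpressionMatrix(
        df, pd.Series("vlinc", index=df.index), pd.Series(1_000, index=df.index)
    )


def make_anns(cats: dict) -> dict:
    return {
        vid: VlincAnnotation(vid, cat, ["p"] if cat != "no_promoter" else [])
        for vid, cat in cats.items()
    }


class TestRmecn:
    def test_identical_expression_gives_ratio_one(self):
        samples = make_samples()
        expr = make_expr({"v1": dict.fromkeys(samples.table.index, 5.0)})
        results, medians, _ = rmecn(expr, samples, make_anns({"v1": LTR}))
        assert results[0].rmecn == 1.0

    def test_simple_ratio(self):
        samples = make_samples(1, 1)
        expr = make_expr({"v1": {"c0": 20.0, "n0": 10.0}})
        results, _, _ = rmecn(expr, samples, make_anns({"v1": NONLTR}))
        assert results[0].rmecn == 2.0

    def test_stem_samples_excluded_from_maxima(self):
        samples = make_samples(1, 1, n_stem=1)
        expr = make_expr({"v1": {"c0": 4.0, "n0": 2.0, "s0": 100.0}})
        results, _, _ = rmecn(expr, samples, make_anns({"v1": LTR}))
        assert results[0].rmecn == 2.0

    def test_zero_normal_max_excluded_and_counted(self):
        samples = make_samples(1, 1)
        expr = make_expr({"v1": {"c0": 3.0, "n0": 0.0}, "v2": {"c0": 4.0, "n0": 2.0}})
        results, medians, n_undef = rmecn(
            expr, samples, make_anns({"v1": LTR, "v2": LTR})
        )
        assert n_undef == 1
        assert medians[LTR] == 2.0

    def test_promoterless_vlincs_not_scored(self):
        samples = make_samples(1, 1)
        expr = make_expr({"v1": {"c0": 3.0, "n0": 1.0}})
        results, _, _ = rmecn(expr, samples, make_anns({"v1": "no_promoter"}))
        assert results == []

    def test_scale_invariance(self, rng):
        samples = make_samples(5, 5)
        data = {f"v{k}": dict(zip(samples.table.index, rng.random(10) + 0.1))
                for k in range(6)}
        anns = make_anns({f"v{k}": LTR if k % 2 else NONLTR for k in range(6)})
        r1, m1, _ = rmecn(make_expr(data), samples, anns)
        scaled = {v: {s: 7.3 * x for s, x in row.items()} for v, row in data.items()}
        r2, m2, _ = rmecn(make_expr(scaled), samples, anns)
        for a, b in zip(r1, r2):
            assert a.rmecn == pytest.approx(b.rmecn, rel=1e-12)
        assert m1[LTR] == pytest.approx(m2[LTR], rel=1e-12)

    def test_planted_boost_recovered_on_fixture(self, metric_world):
        """LTR vlincs boosted x2 in cancer/stem: the LTR/nonLTR ratio of
        median RMECN lands near the planted boost."""
        _, _, _, _, samples, anns, expr = metric_world
        _, medians, _ = rmecn(expr, samples, anns)
        ratio = medians[LTR] / medians[NONLTR]
        assert ratio == pytest.approx(2.0, rel=0.15)


class TestLabelPermutation:
    def test_effect_fixture_beats_every_permutation(self, metric_world):
        _, _, _, _, samples, anns, expr = metric_world
        observed, p, null = label_permutation_test(
            expr, samples, anns, n_perm=199, seed=5
        )
        assert observed > null.max()
        assert p == pytest.approx(1 / 200)

    def test_few_permutations_warn(self, metric_world):
        _, _, _, _, samples, anns, expr = metric_world
        with pytest.warns(UserWarning, match="permutations"):
            label_permutation_test(expr, samples, anns, n_perm=10, seed=1)


class TestMaxLocation:
    def test_recount_matches_oracle(self, rng):
        samples = make_samples(6, 6)
        ids = list(samples.table.index)
        data = {f"v{k}": dict(zip(ids, rng.random(12))) for k in range(20)}
        cats = {f"v{k}": LTR if k < 8 else NONLTR for k in range(20)}
        t, _ = max_location_counts(make_expr(data), samples, make_anns(cats))
        a = sum(
            1 for k in range(8)
            if max(data[f"v{k}"], key=data[f"v{k}"].get).startswith("c")
        )
        c = sum(
            1 for k in range(8, 20)
            if max(data[f"v{k}"], key=data[f"v{k}"].get).startswith("c")
        )
        assert (t.a, t.c) == (a, c)
        assert t.a + t.b == 8 and t.c + t.d == 12

    def test_constant_matrix_warns(self):
        samples = make_samples(2, 2)
        expr = make_expr({"v1": dict.fromkeys(samples.table.index, 1.0)})
        with pytest.warns(UserWarning, match="ties"):
            max_location_counts(expr, samples, make_anns({"v1": LTR}))

    def test_exclude_stem_peaks(self):
        samples = make_samples(1, 1, n_stem=1)
        expr = make_expr(
            {"v1": {"c0": 1.0, "n0": 2.0, "s0": 9.0},
             "v2": {"c0": 5.0, "n0": 2.0, "s0": 1.0}}
        )
        anns = make_anns({"v1": LTR, "v2": LTR})
        t, _ = max_location_counts(expr, samples, anns, exclude_stem_peaks=True)
        assert (t.a, t.b) == (1, 0)


def _frag(start, end, strand="+"):
    return [GenomicInterval("chr1", start, end, strand)]


class TestMassFractions:
    def _tagset(self, positions, informative):
        df = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "strand": "+", "count": 1}
        )
        return TagSet("s1", df, informative)

    def test_empty_set_is_zero(self):
        ts = self._tagset([10, 20], 100)
        out = mass_fractions([ts], {"ltr": []}, [_frag(0, 50)])
        assert out.loc["s1", "ltr_of_informative"] == 0.0

    def test_all_tags_in_set_is_one_of_vlinc_mass(self):
        ts = self._tagset([10, 20, 30], 100)
        sets = {"ltr": [_frag(0, 50)]}
        out = mass_fractions([ts], sets, [_frag(0, 50)])
        assert out.loc["s1", "ltr_of_vlinc_mass"] == 1.0
        assert out.loc["s1", "ltr_of_informative"] == pytest.approx(0.03)

    def test_counting_oracle(self, rng):
        pos = list(rng.integers(0, 1_000, size=200))
        ts = self._tagset(pos, 500)
        sets = {"a": [_frag(0, 300)], "b": [_frag(300, 700)]}
        out = mass_fractions([ts], sets, [_frag(0, 700)])
        n_a = sum(1 for p in pos if p < 300)
        n_b = sum(1 for p in pos if 300 <= p < 700)
        assert out.loc["s1", "a_of_informative"] == pytest.approx(n_a / 500)
        assert out.loc["s1", "b_of_vlinc_mass"] == pytest.approx(
            n_b / (n_a + n_b)
        )
        # disjoint sets: fractions sum to at most 1
        assert (
            out.loc["s1", "a_of_informative"] + out.loc["s1", "b_of_informative"]
            <= 1.0
        )


class TestTopNEnrichment:
    def test_observed_at_expectation_is_central(self, rng):
        samples = make_samples(50, 50)
        ids = list(samples.table.index)
        # alternate ranking: top 20 contains exactly 10 cancers
        fr = pd.Series({s: 100 - i for i, s in enumerate(ids[:10] + ids[50:60]
                        + ids[10:50] + ids[60:])}, dtype=float)
        out = top_n_class_enrichment(fr, samples, n=20)
        assert out["observed"] == 10
        assert 0.2 < out["p"] < 0.8

    def test_deterministic_tie_break(self):
        samples = make_samples(2, 2)
        fr = pd.Series({s: 1.0 for s in samples.table.index})
        out1 = top_n_class_enrichment(fr, samples, n=2)
        out2 = top_n_class_enrichment(fr, samples, n=2)
        assert out1 == out2


class TestClassFractionTests:
    def test_planted_cancer_boost_detected(self, rng):
        samples = make_samples(40, 40)
        vals = {}
        for s in samples.table.index:
            base = rng.normal(0.01, 0.002)
            vals[s] = base + (0.01 if s.startswith("c") else 0.0)
        pmat, medians = class_fraction_tests(pd.Series(vals), samples)
        assert pmat.loc["cancer", "normal"] < 0.01
        assert medians["cancer"] > medians["normal"]

    def test_identical_distributions_not_significant(self, rng):
        samples = make_samples(30, 30)
        vals = pd.Series(dict(zip(samples.table.index, np.tile(rng.random(30), 2))))
        pmat, _ = class_fraction_tests(vals, samples)
        assert pmat.loc["cancer", "normal"] > 0.3


class TestTimecourseTrend:
    def test_perfect_decrease(self):
        t = timecourse_trend(np.linspace(1.0, 0.0, 10))
        assert t.direction == "decrease" and t.p < 1e-12

    def test_flat_series(self):
        t = timecourse_trend([0.5] * 8)
        assert t.p == 1.0

    def test_increasing_series_gets_na_sentinel(self):
        t = timecourse_trend(np.linspace(0.0, 1.0, 10))
        assert t.direction == "increase" and t.p is None

    def test_fixture_ltr_fraction_declines(self, world):
        """TF-coupled LTR vlincs drag the distal-LTR tag mass down across
        the differentiation time course."""
        from vlincworks.annotate import annotate_vlincs
        from vlincworks.quantify import effective_length

        anns = annotate_vlincs(world.bundle)
        frag_of = {
            v.id: effective_length(v, world.bundle)[0]
            for v in world.bundle.vlincs
        }
        ltr = [frag_of[a.vlinc_id] for a in anns.values()
               if a.distal and a.promoter_category == LTR]
        tc = [ts for ts in world.tagsets
              if ts.sample_id in world.truth.timecourse_sample_ids]
        fr = mass_fractions(tc, {"ltr": ltr}, list(frag_of.values()))
        trend = timecourse_trend(fr["ltr_of_informative"].to_numpy())
        assert trend.direction == "decrease"
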