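"""Two-level GO enrichment over a synthetic ontology, plus the generic
interval-overlap enrichment with its intergenic binomial correction."""

import numpy as np
import pandas as pd
import pytest

from vlincworks.go import (
    GeneOntology,
    VlincGoProfile,
    correlated_gene_sets,
    interval_overlap_enrichment,
    make_synthetic_ontology,
    per_vlinc_go_terms,
    subset_enrichment,
)
from vlincworks.intervals import GenomicInterval
from vlincworks.quantify import ExpressionMatrix


def _expr(df: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(
        df, pd.Series("gene", index=df.index), pd.Series(1_000, index=df.index)
    )


class TestOntology:
    def test_ancestor_closure_excludes_root(self):
        onto = GeneOntology({"mid": ("root",), "leaf": ("mid",)}, "root")
        closed = onto.close_annotation({"g": {"leaf"}})
        assert closed["g"] == {"leaf", "mid"}

    def test_synthetic_ontology_is_closed(self):
        onto, gene_go = make_synthetic_ontology(1, [f"g{i}" for i in range(50)])
        for terms in gene_go.values():
            for t in terms:
                assert onto.ancestors(t) - {onto.root} <= terms

    def test_count_monotone_up_the_dag(self):
        onto, gene_go = make_synthetic_ontology(2, [f"g{i}" for i in range(100)])
        counts = {}
        for terms in gene_go.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for term, parents in onto.parents.items():
            for p in parents:
                if p != onto.root:
                    assert counts.get(p, 0) >= counts.get(term, 0)


class TestCorrelatedGeneSets:
    def test_planted_sign_separation(self, rng):
        n = 200
        base = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "pos": base + 0.4 * rng.normal(size=n),
                "neg": -base + 0.4 * rng.normal(size=n),
                "null": rng.normal(size=n),
            }
        ).T
        df = np.exp(df)
        pos, neg = correlated_gene_sets(_expr(df), np.exp(base), list(df.index))
        assert "pos" in pos and "neg" in neg and "null" not in pos + neg

    def test_threshold_above_one_empties_both(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(size=(3, 50))),
                          index=["a", "b", "c"])
        pos, neg = correlated_gene_sets(
            _expr(df), df.loc["a"].to_numpy(), ["b", "c"], threshold=1.01
        )
        assert pos == [] and neg == []

    def test_exact_threshold_included(self):
        # a perfectly correlated gene sits at rho=1 >= any threshold <= 1
        df = pd.DataFrame({"v": [1.0, 2, 3, 4], "g": [2.0, 4, 6, 8]}).T
        pos, _ = correlated_gene_sets(_expr(df), df.loc["v"].to_numpy(), ["g"],
                                      threshold=1.0)
        assert pos == ["g"]


class TestPerVlincTerms:
    def test_maximal_enrichment_kept(self):
        universe = [f"g{i}" for i in range(100)]
        gene_go = {g: {"T"} if i < 8 else {"U"} for i, g in enumerate(universe)}
        kept = per_vlinc_go_terms(universe[:8], gene_go, universe)
        assert "T" in kept and "U" not in kept

    def test_universe_equal_set_nothing_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        gene_go = {g: {"T"} for g in universe}
        assert per_vlinc_go_terms(universe, gene_go, universe) == set()

    def test_empty_gene_set_empty_terms(self):
        assert per_vlinc_go_terms([], {"g": {"T"}}, ["g"]) == set()

    def test_null_calibration_near_five_percent(self, rng):
        """Random gene sets trip ~5% of terms at unadjusted p < 0.05
        (slightly less: the hypergeometric is discrete)."""
        universe = [f"g{i}" for i in range(300)]
        _, gene_go = make_synthetic_ontology(5, universe)
        leaf_terms = {t for ts in gene_go.values() for t in ts
                      if t.startswith("BP:leaf")}
        hits = trials = 0
        for _ in range(60):
            draw = list(rng.choice(universe, size=50, replace=False))
            kept = per_vlinc_go_terms(draw, gene_go, universe)
            hits += len(kept & leaf_terms)
            trials += len(leaf_terms)
        assert 0.01 < hits / trials < 0.08


class TestSubsetEnrichment:
    def _profiles(self, rng, n=200, planted_term="BP:planted", subset_size=50):
        profiles = []
        subset = [f"vg{i}" for i in range(subset_size)]
        for i in range(n):
            vid = f"vg{i}"
            terms = set()
            if vid in subset:
                terms.add(planted_term)
            elif rng.random() < 0.10:
                terms.add(planted_term)
            for t in ("BP:a", "BP:b", "BP:c"):
                if rng.random() < 0.3:
                    terms.add(t)
            profiles.append(VlincGoProfile(vid, terms, set()))
        return profiles, subset

    def test_planted_term_ranks_first(self, rng):
        profiles, subset = self._profiles(rng)
        df = subset_enrichment(profiles, subset, "pos")
        assert df.iloc[0]["term"] == "BP:planted"
        assert df.iloc[0]["p_adj"] < 0.01
        assert df.iloc[0]["Count"] == 50

    def test_subset_equals_background_is_null(self):
        profiles = [VlincGoProfile(f"v{i}", {"T"}, set()) for i in range(10)]
        df = subset_enrichment(profiles, [f"v{i}" for i in range(10)], "pos")
        assert (df["ExpCount"] == df["Count"]).all()
        assert (df["p_raw"] == 1.0).all()

    def test_empty_subset_empty_result(self):
        profiles = [VlincGoProfile("v1", {"T"}, set())]
        assert len(subset_enrichment(profiles, [], "pos")) == 0

    def test_foreign_subset_id_raises(self):
        profiles = [VlincGoProfile("v1", {"T"}, set())]
        with pytest.raises(ValueError, match="not in background"):
            subset_enrichment(profiles, ["zzz"], "pos")

    def test_row_invariants(self, rng):
        profiles, subset = self._profiles(rng)
        df = subset_enrichment(profiles, subset, "pos")
        assert (df["Count"] <= df["Size"]).all()
        assert (df["p_adj"] >= df["p_raw"] - 1e-15).all()
        np.testing.assert_allclose(
            df["ExpCount"], df["Size"] * len(subset) / len(profiles)
        )


class TestIntervalOverlap:
    def test_printed_plug_in_numbers(self):
        """1542 query intervals, 15 overlapping, success probability
        (3.62 + 3)/1542: the binomial upper bound lands at 0.0034."""
        rng = np.random.default_rng(0)
        set_b = [GenomicInterval("chr1", i * 1_000_000, i * 1_000_000 + 5_000)
                 for i in range(60)]
        set_a = []
        for i in range(15):  # overlap the first 15 B intervals
            set_a.append(GenomicInterval("chr1", i * 1_000_000 + 4_000,
                                         i * 1_000_000 + 14_000, "+"))
        for i in range(1527):  # far from any B interval
            s = 70_000_000 + i * 15_000
            set_a.append(GenomicInterval("chr1", s, s + 10_000, "+"))
        out = interval_overlap_enrichment(
            set_a, set_b, genome_length=200_000_000,
            intergenic_length=100_000_000,
            genic_overlaps=3, expected_intergenic=3.62,
        )
        assert out["n_overlapping"] == 15
        assert out["success_prob"] == pytest.approx((3.62 + 3) / 1542)
        assert out["binomial_p"] == pytest.approx(0.0034, abs=0.0002)

    def test_empty_target_set(self):
        set_a = [GenomicInterval("chr1", 0, 10_000)]
        out = interval_overlap_enrichment(
            set_a, [], genome_length=1_000_000, intergenic_length=500_000
        )
        assert out["n_overlapping"] == 0
        assert out["expected_intergenic"] == pytest.approx(0.02)

    def test_expected_count_matches_monte_carlo(self, rng):
        """Uniform placement of each query interval in a contiguous
        intergenic span reproduces the closed-form expectation."""
        G = 1_000_000
        set_b = [GenomicInterval("chr1", 400_000, 450_000)]  # one 50 kb block
        lengths = [500, 1_000, 2_000]
        set_a = [GenomicInterval("chr1", 0, L) for L in lengths]
        out = interval_overlap_enrichment(
            set_a, set_b, genome_length=G, intergenic_length=G
        )
        draws = 10_000
        hits = 0.0
        for L in lengths:
            starts = rng.integers(0, G - L, size=draws)
            hits += np.mean(
                (starts < 450_000) & (starts + L > 400_000)
            )
        assert out["expected_intergenic"] == pytest.approx(hits, rel=0.05)

    def test_too_short_intergenic_space_raises(self):
        set_a = [GenomicInterval("chr1", 0, 10_000)]
        with pytest.raises(ValueError):
            interval_overlap_enrichment(set_a, [], 1_000_000, 5_000)
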