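import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erodescan.enrichment import (GeneModel, associate_regions, bh_fdr,
                                  binomial_region_test, build_domains,
                                  enrich_terms, hypergeom_gene_test,
                                  permutation_overlap_test, rank_terms)
from erodescan.masks import IntervalSet

CHROM = {"chr1": 10_000_000}


class TestBuildDomains:
    def test_plus_strand_basal(self):
        (d,) = build_domains([GeneModel("g", "chr1", 100_000, "+")], CHROM)
        assert (d.basal_start, d.basal_end) == (95_000, 101_000)

    def test_minus_strand_basal(self):
        (d,) = build_domains([GeneModel("g", "chr1", 100_000, "-")], CHROM)
        assert (d.basal_start, d.basal_end) == (99_000, 105_000)

    def test_distant_genes_extend_the_full_megabase(self):
        genes = [GeneModel("a", "chr1", 2_000_000, "+"),
                 GeneModel("b", "chr1", 5_000_000, "+")]
        da, db = build_domains(genes, CHROM)
        assert da.ext_end == da.basal_end + 1_000_000
        assert db.ext_start == db.basal_start - 1_000_000

    def test_extension_stops_at_neighbour_basal(self):
        genes = [GeneModel("a", "chr1", 2_000_000, "+"),
                 GeneModel("b", "chr1", 2_300_000, "+")]
        da, db = build_domains(genes, CHROM)
        assert da.ext_end == db.basal_start
        assert db.ext_start == da.basal_end

    def test_clipping_at_chromosome_bounds(self):
        (d,) = build_domains([GeneModel("g", "chr1", 2_000, "+")], CHROM)
        assert d.basal_start == 0 and d.ext_start == 0

    def test_duplicate_gene_id_is_an_error(self):
        genes = [GeneModel("g", "chr1", 1000, "+"),
                 GeneModel("g", "chr1", 2000, "+")]
        with pytest.raises(ValueError):
            build_domains(genes, CHROM)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 30))
    def test_extended_never_crosses_neighbour_basal(self, seed, n):
        rng = np.random.default_rng(seed)
        tss = sorted(rng.integers(0, CHROM["chr1"], size=n).tolist())
        genes = [GeneModel(f"g{i}", "chr1", t, rng.choice(["+", "-"]))
                 for i, t in enumerate(tss)]
        domains = sorted(build_domains(genes, CHROM), key=lambda d: d.basal_start)
        for d in domains:
            assert d.ext_start <= d.basal_start <= d.basal_end <= d.ext_end
        for a, b in zip(domains, domains[1:]):
            # extension may not reach into a neighbour's basal region beyond
            # its own basal domain
            assert a.ext_end <= max(b.basal_start, a.basal_end)
            assert b.ext_start >= min(a.basal_end, b.basal_start)


class TestAssociateRegions:
    domains = build_domains(
        [GeneModel("a", "chr1", 1_000_000, "+"),
         GeneModel("b", "chr1", 1_200_000, "+")], CHROM)

    def test_region_inside_one_domain(self):
        (genes,) = associate_regions([("chr1", 900_000, 900_100)], self.domains)
        assert genes == ["a"]

    def test_midpoint_in_overlapping_basal_hits_both(self):
        domains = build_domains(
            [GeneModel("a", "chr1", 1_000_000, "+"),
             GeneModel("b", "chr1", 1_002_000, "+")], CHROM)
        (genes,) = associate_regions([("chr1", 999_000, 999_100)], domains)
        assert sorted(genes) == ["a", "b"]

    def test_region_outside_all_domains(self):
        (genes,) = associate_regions([("chr1", 9_000_000, 9_000_100)],
                                     self.domains)
        assert genes == []


class TestBinomialRegionTest:
    def test_exact_tail_example(self):
        p_value, fold = binomial_region_test(10, 5, 0.5)
        assert p_value == pytest.approx(0.623046875)
        assert fold == pytest.approx(1.0)

    def test_zero_hits_gives_one(self):
        assert binomial_region_test(10, 0, 0.3)[0] == 1.0

    def test_single_trial(self):
        p_value, fold = binomial_region_test(1, 1, 0.01)
        assert p_value == pytest.approx(0.01)
        assert fold == pytest.approx(100.0)

    def test_zero_fraction_with_hits_is_an_error(self):
        with pytest.raises(ValueError):
            binomial_region_test(10, 1, 0.0)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.integers(1, 12), st.floats(0.01, 0.99))
    def test_matches_enumeration(self, n, p):
        for k in range(n + 1):
            exact = sum(math.comb(n, j) * p**j * (1 - p)**(n - j)
                        for j in range(k, n + 1))
            got, _ = binomial_region_test(n, k, p)
            assert got == pytest.approx(exact, rel=1e-9)


class TestHypergeomGeneTest:
    def test_exact_example(self):
        assert hypergeom_gene_test(10, 2, 2, 2) == pytest.approx(1 / 45)

    def test_zero_hits_gives_one(self):
        assert hypergeom_gene_test(10, 3, 4, 0) == 1.0

    def test_term_equals_universe(self):
        assert hypergeom_gene_test(10, 10, 4, 4) == pytest.approx(1.0)

    def test_inconsistent_counts_are_an_error(self):
        with pytest.raises(ValueError):
            hypergeom_gene_test(10, 2, 2, 3)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.integers(1, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration(self, N, K, n):
        K, n = min(K, N), min(n, N)
        for k in range(min(K, n) + 1):
            exact = sum(math.comb(K, j) * math.comb(N - K, n - j)
                        for j in range(k, min(K, n) + 1)
                        if n - j <= N - K) / math.comb(N, n)
            assert hypergeom_gene_test(N, K, n, k) == pytest.approx(exact, rel=1e-9)


class TestBhFdr:
    def test_step_up_recursion(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_qvalues_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestRankTerms:
    def frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"term_id": "good", "fold": 2.85, "region_q": 1e-4, "gene_q": 1e-3},
            {"term_id": "low_fold", "fold": 1.9, "region_q": 1e-9, "gene_q": 1e-9},
            {"term_id": "gene_q_fail", "fold": 3.0, "region_q": 0.04, "gene_q": 0.2},
        ])

    def test_all_three_gates_enforced(self):
        sig = rank_terms(self.frame())
        assert list(sig["term_id"]) == ["good"]


class TestPermutationOverlap:
    allowed = {"chr1": IntervalSet.from_pairs([(0, 1_000_000)])}

    def test_features_covering_all_space_give_p_one_fold_one(self):
        regions = [("chr1", i * 1000, i * 1000 + 50) for i in range(10)]
        features = {"chr1": IntervalSet.from_pairs([(0, 1_000_000)])}
        res = permutation_overlap_test(regions, features, self.allowed,
                                       m=200, seed=0)
        assert res.p_value == 1.0
        assert res.fold == pytest.approx(1.0)

    def test_observed_above_all_permutations_hits_the_floor(self):
        # regions sit exactly on the only features; random placements in the
        # 1 Mb allowed space almost never do
        regions = [("chr1", i * 10_000, i * 10_000 + 20) for i in range(8)]
        features = {"chr1": IntervalSet.from_pairs(
            [(r[1], r[2]) for r in regions])}
        res = permutation_overlap_test(regions, features, self.allowed,
                                       m=500, seed=1)
        assert res.b == 0
        assert res.p_value == pytest.approx(1 / 501)

    def test_p_follows_add_one_formula(self):
        rng = np.random.default_rng(3)
        regions = [("chr1", int(s), int(s) + 100)
                   for s in rng.integers(0, 900_000, size=12)]
        features = {"chr1": IntervalSet.from_pairs(
            [(int(s), int(s) + 5000) for s in rng.integers(0, 900_000, size=40)])}
        res = permutation_overlap_test(regions, features, self.allowed,
                                       m=99, seed=4)
        assert res.p_value == pytest.approx((res.b + 1) / 100)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_deterministic_for_a_seed(self):
        regions = [("chr1", 100, 200), ("chr1", 5000, 5100)]
        features = {"chr1": IntervalSet.from_pairs([(0, 10_000)])}
        a = permutation_overlap_test(regions, features, self.allowed, m=50, seed=9)
        b = permutation_overlap_test(regions, features, self.allowed, m=50, seed=9)
        assert a == b

    def test_oversized_regions_are_an_error(self):
        regions = [("chr1", 0, 2_000_000)]
        with pytest.raises(ValueError):
            permutation_overlap_test(regions, {}, self.allowed, m=10, seed=0)


class TestEnrichTerms:
    def test_planted_concentration_is_detected(self):
        rng = np.random.default_rng(0)
        genes = [GeneModel(f"g{i}", "chr1", 50_000 + i * 100_000, "+")
                 for i in range(30)]
        terms = {"hit": [f"g{i}" for i in range(10)],
                 "other": [f"g{i}" for i in range(15, 29)]}
        # regions concentrated near the first ten genes
        regions = [("chr1", 50_000 + (i % 10) * 100_000 + 2000,
                    50_000 + (i % 10) * 100_000 + 2100) for i in range(25)]
        df = enrich_terms(regions, genes, terms, {"chr1": 3_100_000})
        top = df.iloc[0]
        assert top["term_id"] == "hit"
        assert top["fold"] > 2
        assert top["region_q"] < 0.05
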