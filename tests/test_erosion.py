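import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erodescan.alignment import AlignmentBlock
from erodescan.erosion import (IndependentSet, OutgroupSpec, call_eroded,
                               classify_mechanism, dedup_overlaps,
                               intersect_independent, mechanism_table,
                               rank_top_k)
from erodescan.masks import IntervalSet
from erodescan.phylo import parse_newick
from erodescan.prediction import ConservedSite

TREE = parse_newick(
    "(((ref:0.3,A:0.3):0.3,(t1:0.4,o1:0.4):0.3):0.2,(t2:0.6,o2:0.6):0.5);")


def site(start=10, end=18, matching=("ref", "A", "o1", "o2"), p=1e-4,
         bbl=3.5, motif="M", strand="+", chrom="chr1"):
    return ConservedSite(chrom=chrom, start=start, end=end, strand=strand,
                         motif_id=motif, matching_species=frozenset(matching),
                         bbl=bbl, conservation_bin=50, empirical_p=p)


def covering_block(target_row="AAAAAAAA", width=30, start=0):
    rows = {sp: "A" * width for sp in TREE.leaves}
    rows["t1"] = "A" * 10 + target_row + "A" * (width - 10 - len(target_row))
    return AlignmentBlock(ref_species="ref", ref_chrom="chr1",
                          ref_start=start, rows=rows)


class TestCallEroded:
    spec = OutgroupSpec(target="t1", outgroups=frozenset({"o1"}))

    def test_site_present_in_target_is_not_eroded(self):
        s = site(matching=("ref", "A", "t1", "o1"))
        assert call_eroded([s], self.spec, [covering_block()], TREE) == []

    def test_absent_in_target_present_in_outgroup_is_eroded(self):
        s = site(matching=("ref", "A", "o1", "o2"))
        (e,) = call_eroded([s], self.spec, [covering_block()], TREE)
        assert e.target == "t1" and e.site is s

    def test_no_outgroup_support_is_not_eroded(self):
        s = site(matching=("ref", "A", "o2"))
        assert call_eroded([s], self.spec, [covering_block()], TREE) == []

    def test_target_assembly_gap_discards_site(self):
        blk = covering_block(target_row="NNNNNNNN")  # Ns over [10, 18)
        s = site(matching=("ref", "A", "o1"))
        assert call_eroded([s], self.spec, [blk], TREE) == []

    def test_target_gap_bed_discards_site(self):
        s = site(matching=("ref", "A", "o1"))
        gaps = {"chr1": IntervalSet.from_pairs([(12, 14)])}
        assert call_eroded([s], self.spec, [covering_block()], TREE,
                           target_gaps=gaps) == []

    def test_unknown_species_is_an_error(self):
        bad = OutgroupSpec(target="zz", outgroups=frozenset({"o1"}))
        with pytest.raises(KeyError):
            call_eroded([site()], bad, [covering_block()], TREE)

    def test_target_cannot_be_outgroup(self):
        with pytest.raises(ValueError):
            OutgroupSpec(target="t1", outgroups=frozenset({"t1"}))


class TestIntersectIndependent:
    def eroded(self, target, sites):
        from erodescan.erosion import ErodedSite
        return [ErodedSite(site=s, target=target) for s in sites]

    def test_site_eroded_in_one_lineage_only_is_excluded(self):
        a, b = site(start=10), site(start=50, end=58)
        ind = intersect_independent(
            [self.eroded("t1", [a, b]), self.eroded("t2", [a])], ["t1", "t2"])
        assert [s.start for s in ind.sites] == [10]

    def test_three_lineages_require_all_three(self):
        a, b = site(start=10), site(start=50, end=58)
        ind = intersect_independent(
            [self.eroded("t1", [a, b]), self.eroded("t2", [a, b]),
             self.eroded("t3", [b])], ["t1", "t2", "t3"])
        assert [s.start for s in ind.sites] == [50]

    def test_fewer_than_two_sets_is_an_error(self):
        with pytest.raises(ValueError):
            intersect_independent([self.eroded("t1", [site()])], ["t1"])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_set_algebra_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        catalog = [site(start=int(i * 20), end=int(i * 20 + 8)) for i in range(15)]
        pick1 = [s for s in catalog if rng.random() < 0.5]
        pick2 = [s for s in catalog if rng.random() < 0.5]
        ind = intersect_independent(
            [self.eroded("t1", pick1), self.eroded("t2", pick2)], ["t1", "t2"])
        expected = {s.key for s in pick1} & {s.key for s in pick2}
        assert {s.key for s in ind.sites} == expected


class TestRankTopK:
    def make(self, pvals):
        sites = [site(start=i * 20, end=i * 20 + 8, p=p)
                 for i, p in enumerate(pvals)]
        return IndependentSet(targets=("t1", "t2"), sites=sites)

    def test_ties_at_the_cutoff_are_kept(self):
        ind = self.make([1e-5, 1e-4, 1e-3, 1e-3, 1e-2])
        assert len(rank_top_k(ind, k=3)) == 4

    def test_fewer_sites_than_k_returns_all(self):
        ind = self.make([0.1, 0.2])
        assert len(rank_top_k(ind, k=5000)) == 2

    def test_all_tied_returns_all(self):
        ind = self.make([1e-3] * 5)
        assert len(rank_top_k(ind, k=2)) == 5

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_top_k(self.make([0.1]), k=0)


def greedy_oracle(sites):
    """Reference greedy dedup: explicit O(n^2) pairwise overlap checks."""
    order = sorted(sites, key=lambda s: (s.empirical_p, -s.bbl, s.chrom,
                                         s.start, s.end, s.strand, s.motif_id))
    kept = []
    for s in order:
        if all(s.chrom != k.chrom or s.end <= k.start or k.end <= s.start
               for k in kept):
            kept.append(s)
    return {s.key for s in kept}


class TestDedupOverlaps:
    def ind(self, sites):
        return IndependentSet(targets=("t1", "t2"), sites=sites)

    def test_better_of_two_overlapping_sites_wins(self):
        a = site(start=10, end=18, p=1e-5)
        b = site(start=14, end=22, p=1e-4)
        out = dedup_overlaps(self.ind([a, b]))
        assert [s.start for s in out.sites] == [10]

    def test_chain_keeps_both_ends(self):
        a = site(start=10, end=18, p=1e-6)
        b = site(start=16, end=24, p=1e-3)
        c = site(start=22, end=30, p=1e-5)
        out = dedup_overlaps(self.ind([a, b, c]))
        assert [s.start for s in out.sites] == [10, 22]

    def test_disjoint_sites_all_kept(self):
        sites = [site(start=i * 100, end=i * 100 + 8) for i in range(5)]
        assert len(dedup_overlaps(self.ind(sites))) == 5

    def test_output_is_maximal(self):
        rng = np.random.default_rng(1)
        sites = [site(start=int(s), end=int(s) + 8,
                      p=float(rng.random()))
                 for s in rng.integers(0, 60, size=12)]
        out = dedup_overlaps(self.ind(sites))
        kept = out.sites
        for s in sites:
            if s in kept:
                continue
            assert any(s.chrom == k.chrom and s.start < k.end and k.start < s.end
                       for k in kept)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 20))
    def test_matches_greedy_oracle_on_random_clusters(self, seed, n):
        rng = np.random.default_rng(seed)
        sites = [site(start=int(s), end=int(s + rng.integers(4, 12)),
                      p=float(rng.choice([1e-5, 1e-4, 1e-3])),
                      bbl=float(rng.random() * 4))
                 for s in rng.integers(0, 80, size=n)]
        # ensure distinct identities
        sites = list({s.key: s for s in sites}.values())
        out = dedup_overlaps(self.ind(sites))
        assert {s.key for s in out.sites} == greedy_oracle(sites)


class TestClassifyMechanism:
    def test_partially_aligned_target_is_mismatch(self):
        blk = covering_block(target_row="ACG-TACG")
        assert classify_mechanism(site(), [blk], "t1") == "mismatch"

    def test_fully_gapped_target_is_deletion(self):
        blk = covering_block(target_row="--------")
        assert classify_mechanism(site(), [blk], "t1") == "deletion"

    def test_target_absent_from_blocks_is_deletion(self):
        rows = {sp: "A" * 30 for sp in TREE.leaves if sp != "t1"}
        blk = AlignmentBlock(ref_species="ref", ref_chrom="chr1",
                             ref_start=0, rows=rows)
        assert classify_mechanism(site(), [blk], "t1") == "deletion"

    def test_single_aligned_base_is_mismatch(self):
        blk = covering_block(target_row="-------G")
        assert classify_mechanism(site(), [blk], "t1") == "mismatch"


class TestMechanismTable:
    def test_cross_tabulation(self):
        a, b = site(start=10), site(start=50, end=58)
        ind = IndependentSet(
            targets=("t1", "t2"), sites=[a, b],
            mechanisms={a.key: {"t1": "mismatch", "t2": "mismatch"},
                        b.key: {"t1": "mismatch", "t2": "deletion"}})
        assert mechanism_table(ind) == \
            {"all_mismatch": 1, "mixed": 1, "all_deletion": 0}

    def test_counts_sum_to_set_size(self, small_screen):
        counts = mechanism_table(small_screen.independent)
        assert sum(counts.values()) == len(small_screen.independent)

    def test_missing_classification_is_an_error(self):
        a = site()
        ind = IndependentSet(targets=("t1", "t2"), sites=[a], mechanisms={})
        with pytest.raises(ValueError):
            mechanism_table(ind)
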