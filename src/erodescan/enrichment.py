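"""Region and gene enrichment of eroded-site sets, GREAT style.

Each gene owns a *basal* regulatory domain around its TSS (5 kb upstream,
1 kb downstream, strand-aware) extended in both directions up to 1 Mb but
stopping at the nearest neighbouring basal domain.  A query region is
associated with every gene whose extended domain contains the region's
midpoint.  Per ontology term, region hits are tested with a binomial against
the term's annotated genome fraction, gene hits with a hypergeometric over
the gene universe; both are BH-corrected, and a term is called significant
at region fold ≥ 2 with both FDRs ≤ 0.05.

The overlap of a region set with a feature track (e.g. regulatory marks) is
assessed with a permutation test: length-preserving, mutually non-overlapping
placements uniform over the allowed space, with the Phipson–Smyth add-one
P-value (b + 1) / (m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .masks import IntervalSet

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "PermutationResult",
    "build_domains",
    "associate_regions",
    "binomial_region_test",
    "hypergeom_gene_test",
    "bh_fdr",
    "enrich_terms",
    "rank_terms",
    "permutation_overlap_test",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int


def build_domains(genes: list[GeneModel], chrom_sizes: dict[str, int],
                  basal_up: int = 5000, basal_down: int = 1000,
                  max_extension: int = 1_000_000) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal domain is ``[tss - basal_up, tss + basal_down)`` for + strand
    genes and ``[tss - basal_down, tss + basal_up)`` for − strand, clipped to
    the chromosome.  Extension grows each side by up to ``max_extension`` but
    stops at the nearest neighbouring basal domain boundary, never shrinking
    below the gene's own basal domain.
    """
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)

    out: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        size = chrom_sizes[chrom]
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        basal = []
        for g in gs:
            if g.strand == "+":
                s, e = g.tss - basal_up, g.tss + basal_down
            else:
                s, e = g.tss - basal_down, g.tss + basal_up
            basal.append((max(0, s), min(size, e)))
        for i, g in enumerate(gs):
            bs, be = basal[i]
            ext_s = bs - max_extension
            ext_e = be + max_extension
            if i > 0:
                ext_s = max(ext_s, basal[i - 1][1])
            if i + 1 < len(gs):
                ext_e = min(ext_e, basal[i + 1][0])
            ext_s = min(max(ext_s, 0), bs)   # never shrink below basal
            ext_e = max(min(ext_e, size), be)
            out.append(RegulatoryDomain(g.gene_id, chrom, bs, be, ext_s, ext_e))
    return out


def associate_regions(regions: list[tuple[str, int, int]],
                      domains: list[RegulatoryDomain]) -> list[list[str]]:
    """Gene associations per region: every gene whose extended domain
    contains the region's midpoint."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    arrs = {}
    for chrom, ds in by_chrom.items():
        arrs[chrom] = (np.array([d.ext_start for d in ds]),
                       np.array([d.ext_end for d in ds]),
                       [d.gene_id for d in ds])
    out: list[list[str]] = []
    for chrom, start, end in regions:
        if chrom not in arrs:
            out.append([])
            continue
        mid = (start + end) // 2
        s, e, ids = arrs[chrom]
        hit = (s <= mid) & (mid < e)
        out.append([ids[i] for i in np.flatnonzero(hit)])
    return out


def term_genome_fraction(term_genes, domains: list[RegulatoryDomain],
                         genome_size: int) -> float:
    """Fraction of the genome covered by the union of the term's extended
    regulatory domains."""
    members = set(term_genes)
    ivs = IntervalSet.from_pairs(
        (d.ext_start, d.ext_end) for d in domains if d.gene_id in members)
    return ivs.total_length() / genome_size


def binomial_region_test(n_regions: int, term_hits: int, genome_fraction: float
                         ) -> tuple[float, float]:
    """Upper-tail binomial P(X ≥ k) for k of n regions hitting a term whose
    domains cover ``genome_fraction`` of the genome, plus the fold
    ``k / (n * p)``."""
    if not 0.0 <= genome_fraction <= 1.0:
        raise ValueError("genome fraction outside [0, 1]")
    if term_hits > n_regions:
        raise ValueError("more hits than regions")
    if genome_fraction == 0.0:
        if term_hits > 0:
            raise ValueError("hits observed for a term with zero genome fraction")
        return 1.0, 0.0
    if term_hits == 0:
        return 1.0, 0.0
    p_value = float(stats.binom.sf(term_hits - 1, n_regions, genome_fraction))
    fold = term_hits / (n_regions * genome_fraction)
    return p_value, fold


def hypergeom_gene_test(universe_size: int, term_size: int,
                        hit_genes: int, term_hits: int) -> float:
    """Upper-tail hypergeometric P(X ≥ k): of ``hit_genes`` genes picked from
    a universe of ``universe_size`` containing ``term_size`` term genes, the
    probability of ``term_hits`` or more term genes."""
    if term_hits > min(term_size, hit_genes) or term_size > universe_size \
            or hit_genes > universe_size or min(universe_size, term_size,
                                                hit_genes, term_hits) < 0:
        raise ValueError("inconsistent hypergeometric counts")
    if term_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(term_hits - 1, universe_size, term_size, hit_genes))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-value outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(regions: list[tuple[str, int, int]], genes: list[GeneModel],
                 terms: dict[str, list[str]], chrom_sizes: dict[str, int],
                 basal_up: int = 5000, basal_down: int = 1000,
                 max_extension: int = 1_000_000,
                 min_term_genes: int = 10, max_term_genes: int = 500,
                 domains: list[RegulatoryDomain] | None = None) -> pd.DataFrame:
    """Region- and gene-based enrichment of every eligible ontology term.

    Terms are filtered to ``min_term_genes``–``max_term_genes`` genes after
    intersection with the universe (all genes with domains).  Returns one row
    per tested term with hit counts, genome fraction, fold, binomial and
    hypergeometric P-values and BH q-values over exactly the tested terms.
    """
    if domains is None:
        domains = build_domains(genes, chrom_sizes, basal_up, basal_down, max_extension)
    universe = {d.gene_id for d in domains}
    genome_size = sum(chrom_sizes.values())
    assoc = associate_regions(regions, domains)
    hit_gene_sets = [set(a) for a in assoc]
    all_hit_genes = set().union(*hit_gene_sets) if hit_gene_sets else set()

    rows = []
    for term_id, members in terms.items():
        members = set(members) & universe
        if not min_term_genes <= len(members) <= max_term_genes:
            continue
        region_hits = sum(1 for h in hit_gene_sets if h & members)
        frac = term_genome_fraction(members, domains, genome_size)
        binom_p, fold = binomial_region_test(len(regions), region_hits, frac)
        gene_hits = len(all_hit_genes & members)
        hyper_p = hypergeom_gene_test(len(universe), len(members),
                                      len(all_hit_genes), gene_hits)
        rows.append({
            "term_id": term_id, "term_size": len(members),
            "n_regions": len(regions), "region_hits": region_hits,
            "genome_fraction": frac, "fold": fold, "binom_p": binom_p,
            "gene_hits": gene_hits, "hyper_p": hyper_p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["region_q"] = bh_fdr(df["binom_p"].to_numpy())
        df["gene_q"] = bh_fdr(df["hyper_p"].to_numpy())
        df = df.sort_values(["region_q", "binom_p", "fold"],
                            ascending=[True, True, False],
                            kind="stable").reset_index(drop=True)
    return df


def rank_terms(results: pd.DataFrame, fold_min: float = 2.0,
               q_max: float = 0.05) -> pd.DataFrame:
    """Significant terms: region fold ≥ ``fold_min`` and both FDRs ≤
    ``q_max``, most enriched (lowest region q, then highest fold) first."""
    if len(results) == 0:
        return results
    sig = results[(results["fold"] >= fold_min)
                  & (results["region_q"] <= q_max)
                  & (results["gene_q"] <= q_max)]
    return sig.sort_values(["region_q", "fold"], ascending=[True, False],
                           kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    m: int
    b: int            # permutations with statistic >= observed
    p_value: float
    fold: float
    perm_mean: float


def permutation_overlap_test(regions: list[tuple[str, int, int]],
                             features: dict[str, IntervalSet],
                             allowed: dict[str, IntervalSet],
                             m: int = 10_000, seed: int = 0,
                             max_retries: int = 1000) -> PermutationResult:
    """Permutation test of region/feature overlap.

    Each permutation re-places every region — lengths preserved — uniformly
    at random inside the allowed space, regions mutually non-overlapping.
    The statistic is the number of regions overlapping at least one feature;
    the P-value is the Phipson–Smyth (b + 1) / (m + 1).

    Placement is rejection sampling done jointly over permutations: the
    allowed intervals are laid out on one global axis, all candidate starts
    are drawn at once, and only permutations with internal overlaps are
    redrawn (up to ``max_retries`` rounds).
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(allowed)
    seg_start, seg_len, glob_off = [], [], []
    gfeat_pairs: list[tuple[int, int]] = []
    off = 0
    for c in chroms:
        ivs = allowed[c]
        feat = features.get(c)
        for s, e in zip(ivs.starts.tolist(), ivs.ends.tolist()):
            seg_start.append(s)
            seg_len.append(e - s)
            glob_off.append(off)
            if feat is not None and len(feat):
                # features clipped to this segment, shifted to global coords
                lo = np.maximum(feat.starts, s)
                hi = np.minimum(feat.ends, e)
                for fs, fe in zip(lo.tolist(), hi.tolist()):
                    if fe > fs:
                        gfeat_pairs.append((fs - s + off, fe - s + off))
            off += e - s
    seg_start = np.array(seg_start, dtype=np.int64)
    seg_len = np.array(seg_len, dtype=np.int64)
    glob_off = np.array(glob_off, dtype=np.int64)
    gfeat = IntervalSet.from_pairs(gfeat_pairs)

    lengths = np.array([e - s for _, s, e in regions], dtype=np.int64)
    n = len(lengths)
    if n == 0:
        raise ValueError("no regions to permute")
    if lengths.sum() > seg_len.sum():
        raise ValueError("regions exceed the allowed space")

    observed = 0
    for c, s, e in regions:
        feat = features.get(c)
        if feat is not None and feat.overlaps(s, e):
            observed += 1

    # per-region cumulative segment weights (number of valid start positions)
    cum_by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ln in np.unique(lengths):
        nstarts = np.maximum(seg_len - int(ln) + 1, 0)
        if nstarts.sum() == 0:
            raise ValueError(f"no allowed interval can hold a region of length {ln}")
        cum = np.cumsum(nstarts / nstarts.sum())
        cum_by_len[int(ln)] = (cum, nstarts)

    gstarts = np.empty((m, n), dtype=np.int64)
    todo = np.arange(m)
    for _round in range(max_retries):
        t = len(todo)
        if t == 0:
            break
        for i in range(n):
            cum, nstarts = cum_by_len[int(lengths[i])]
            seg = np.searchsorted(cum, rng.random(t), side="right")
            seg = np.minimum(seg, len(cum) - 1)
            pos = (rng.random(t) * nstarts[seg]).astype(np.int64)
            gstarts[todo, i] = glob_off[seg] + pos
        rows = gstarts[todo]
        order = np.argsort(rows, axis=1, kind="stable")
        ss = np.take_along_axis(rows, order, axis=1)
        ee = ss + lengths[order]
        clash = (ee[:, :-1] > ss[:, 1:]).any(axis=1)
        todo = todo[clash]
    else:
        if len(todo):
            raise ValueError("could not place shuffled regions without overlap; "
                             "allowed space too dense")

    gends = gstarts + lengths[None, :]
    if len(gfeat):
        i = np.searchsorted(gfeat.ends, gstarts.ravel(), side="right")
        hit = i < len(gfeat.starts)
        hit[hit] &= gfeat.starts[i[hit]] < gends.ravel()[hit]
        stats_out = hit.reshape(m, n).sum(axis=1)
    else:
        stats_out = np.zeros(m, dtype=np.int64)

    b = int((stats_out >= observed).sum())
    p = (b + 1) / (m + 1)
    perm_mean = float(stats_out.mean())
    if perm_mean > 0:
        fold = observed / perm_mean
    else:
        fold = 1.0 if observed == 0 else float("inf")
    return PermutationResult(observed=observed, m=m, b=b, p_value=p,
                             fold=fold, perm_mean=perm_mean)
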