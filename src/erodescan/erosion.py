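"""Lineage-specific erosion calls and the independent-erosion intersection.

A conserved site is *eroded* in a target species when the motif match is
absent in the target but present in at least one designated outgroup —
evidence that the ancestor of the clade carried the site and the target lost
it.  Calls whose target sequence overlaps an assembly gap are discarded as
unscorable.  Sites eroded in every target lineage form the independent set,
which is ranked by excess-conservation P, truncated to the top k (keeping
ties at the cutoff), made non-overlapping, and classified by mechanism:
*mismatch* if any target sequence still aligns, *deletion* if none does.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentBlock, GAP_CODE, N_CODE
from .masks import IntervalSet
from .phylo import PhyloTree
from .prediction import ConservedSite

__all__ = [
    "OutgroupSpec",
    "ErodedSite",
    "IndependentSet",
    "call_eroded",
    "intersect_independent",
    "rank_top_k",
    "dedup_overlaps",
    "classify_mechanism",
    "mechanism_table",
]

MISMATCH = "mismatch"
DELETION = "deletion"


@dataclass(frozen=True)
class OutgroupSpec:
    """One target species and its outgroups (sister species retaining the
    ancestral state)."""

    target: str
    outgroups: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outgroups", frozenset(self.outgroups))
        if not self.outgroups:
            raise ValueError("at least one outgroup is required")
        if self.target in self.outgroups:
            raise ValueError("target cannot be its own outgroup")

    def validate(self, tree: PhyloTree) -> None:
        for name in {self.target, *self.outgroups}:
            tree.leaf_index(name)


@dataclass(frozen=True)
class ErodedSite:
    """A conserved site eroded in one target species."""

    site: ConservedSite
    target: str
    mechanism: str | None = None

    @property
    def key(self) -> tuple:
        return self.site.key


@dataclass
class IndependentSet:
    """Sites eroded in every target lineage, with per-target mechanisms."""

    targets: tuple[str, ...]
    sites: list[ConservedSite]
    mechanisms: dict[tuple, dict[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)


class _BlockIndex:
    """Lookup of the alignment block covering a reference interval."""

    def __init__(self, blocks):
        self._by_chrom: dict[str, list[AlignmentBlock]] = {}
        for blk in blocks:
            self._by_chrom.setdefault(blk.ref_chrom, []).append(blk)
        self._starts = {}
        for chrom, blks in self._by_chrom.items():
            blks.sort(key=lambda b: b.ref_start)
            self._starts[chrom] = [b.ref_start for b in blks]

    def covering(self, chrom: str, start: int, end: int) -> list[AlignmentBlock]:
        blks = self._by_chrom.get(chrom, [])
        if not blks:
            return []
        starts = self._starts[chrom]
        i = bisect_left(starts, end)
        out = []
        for blk in blks[max(0, i - len(blks)):i]:
            if blk.ref_end > start:
                out.append(blk)
        return out


def _target_codes(index: _BlockIndex, site: ConservedSite, target: str) -> np.ndarray:
    """Encoded target characters over the site's alignment columns, pieced
    together from all covering blocks (empty if the target never aligns)."""
    pieces = []
    for blk in index.covering(site.chrom, site.start, site.end):
        lo = max(site.start, blk.ref_start)
        hi = min(site.end, blk.ref_end)
        if hi <= lo or target not in blk.species:
            continue
        pieces.append(blk.species_codes(target, lo, hi))
    if not pieces:
        return np.empty(0, dtype=np.int8)
    return np.concatenate(pieces)


def call_eroded(sites, spec: OutgroupSpec, blocks, tree: PhyloTree,
                target_gaps: dict[str, "IntervalSet"] | None = None) -> list[ErodedSite]:
    """Eroded-site calls for one target lineage.

    Keeps a site iff the target does not match, at least one outgroup does,
    and the target sequence shows no assembly gap over the site (no 'N' in
    the aligned target rows and no overlap with ``target_gaps``, an optional
    per-chromosome gap mask for this target in reference coordinates).
    """
    spec.validate(tree)
    index = _BlockIndex(blocks)
    out: list[ErodedSite] = []
    for site in sites:
        if spec.target in site.matching_species:
            continue
        if not (site.matching_species & spec.outgroups):
            continue
        codes = _target_codes(index, site, spec.target)
        if (codes == N_CODE).any():
            continue
        if target_gaps and site.chrom in target_gaps and \
                target_gaps[site.chrom].overlaps(site.start, site.end):
            continue
        out.append(ErodedSite(site=site, target=spec.target))
    return out


def intersect_independent(eroded_sets: list[list[ErodedSite]],
                          targets: list[str]) -> IndependentSet:
    """Sites eroded in *every* target lineage (same interval+motif+strand)."""
    if len(eroded_sets) < 2:
        raise ValueError("independent erosion needs at least two target lineages")
    if len(eroded_sets) != len(targets):
        raise ValueError("one eroded-site list per target is required")
    keys = [set(e.key for e in es) for es in eroded_sets]
    shared = set.intersection(*keys)
    by_key = {e.key: e.site for e in eroded_sets[0]}
    sites = sorted((by_key[k] for k in shared),
                   key=lambda s: (s.chrom, s.start, s.end, s.strand, s.motif_id))
    return IndependentSet(targets=tuple(targets), sites=sites)


def _rank_key(site: ConservedSite) -> tuple:
    # lower empirical p first; tie-break: higher BBL, then leftmost coordinate
    return (site.empirical_p, -site.bbl, site.chrom, site.start, site.end,
            site.strand, site.motif_id)


def rank_top_k(ind: IndependentSet, k: int = 5000) -> IndependentSet:
    """Top-k sites by excess-conservation P, plus all sites tied with the
    k-th at the cutoff P-value (no arbitrary tie-breaking at the boundary)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(ind.sites, key=_rank_key)
    if len(ranked) > k:
        cutoff = ranked[k - 1].empirical_p
        n = k
        while n < len(ranked) and ranked[n].empirical_p == cutoff:
            n += 1
        ranked = ranked[:n]
    return IndependentSet(targets=ind.targets, sites=ranked,
                          mechanisms=dict(ind.mechanisms))


def dedup_overlaps(ind: IndependentSet) -> IndependentSet:
    """Greedy non-overlap filter: walk sites from most to least significant
    and keep each iff it overlaps no already-kept site (strand-agnostic,
    half-open intervals)."""
    kept: list[ConservedSite] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for site in sorted(ind.sites, key=_rank_key):
        ivs = by_chrom.setdefault(site.chrom, [])
        i = bisect_left(ivs, (site.start, site.start))
        clash = (i < len(ivs) and ivs[i][0] < site.end) or \
                (i > 0 and ivs[i - 1][1] > site.start)
        if clash:
            continue
        insort(ivs, (site.start, site.end))
        kept.append(site)
    kept.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand, s.motif_id))
    return IndependentSet(targets=ind.targets, sites=kept,
                          mechanisms=dict(ind.mechanisms))


def classify_mechanism(site: ConservedSite, blocks, target: str) -> str:
    """Mismatch if any target base aligns over the site; else deletion."""
    index = blocks if isinstance(blocks, _BlockIndex) else _BlockIndex(blocks)
    codes = _target_codes(index, site, target)
    aligned = codes[(codes != GAP_CODE)]
    return MISMATCH if len(aligned) > 0 else DELETION


def classify_all(ind: IndependentSet, blocks) -> IndependentSet:
    """Per-target mechanism for every site in the independent set."""
    index = _BlockIndex(blocks)
    mech = {}
    for site in ind.sites:
        mech[site.key] = {t: classify_mechanism(site, index, t) for t in ind.targets}
    return IndependentSet(targets=ind.targets, sites=list(ind.sites), mechanisms=mech)


def mechanism_table(ind: IndependentSet) -> dict[str, int]:
    """Cross-tabulation of per-target mechanisms.

    ``all_mismatch`` / ``all_deletion`` count sites where every target shows
    the same mechanism; ``mixed`` counts the rest.  Counts sum to the set
    size.
    """
    counts = {"all_mismatch": 0, "mixed": 0, "all_deletion": 0}
    for site in ind.sites:
        mechs = ind.mechanisms.get(site.key)
        if mechs is None or len(mechs) != len(ind.targets):
            raise ValueError("mechanism classification missing for a site")
        vals = set(mechs.values())
        if vals == {MISMATCH}:
            counts["all_mismatch"] += 1
        elif vals == {DELETION}:
            counts["all_deletion"] += 1
        else:
            counts["mixed"] += 1
    return counts
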