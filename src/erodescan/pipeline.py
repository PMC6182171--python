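"""End-to-end orchestration of the erosion screen.

``run_screen`` chains the stages in their natural order: conservation
profile → shuffled-motif nulls → conserved-site calls → per-lineage erosion
calls → intersection across lineages → ranking, dedup and mechanism
classification → ontology enrichment → feature-overlap permutation test.
Every stage is a pure function of its inputs, the parameter block and the
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .alignment import ConservationProfile, build_conservation_profile
from .enrichment import (PermutationResult, enrich_terms, permutation_overlap_test,
                         rank_terms)
from .erosion import (IndependentSet, OutgroupSpec, call_eroded, classify_all,
                      dedup_overlaps, intersect_independent, mechanism_table,
                      rank_top_k)
from .masks import GenomeMask, IntervalSet
from .prediction import NullDistribution, build_null, predict_sites

logger = logging.getLogger("erodescan")


@dataclass
class ScreenParams:
    """Parameter block; defaults are the screen's standard operating values."""

    match_threshold: float = 0.8
    p_max: float = 1e-3
    min_species: int = 5
    min_bbl: float = 3.0
    top_k: int = 5000
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    fold_min: float = 2.0
    q_max: float = 0.05
    n_permutations: int = 10_000
    n_shuffles: int = 30
    null_min_count: int = 1000
    smoothing_window: int = 100
    min_term_genes: int = 10
    max_term_genes: int = 500

    def validate(self) -> None:
        if not 0 < self.match_threshold <= 1:
            raise ValueError("match_threshold must be in (0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.min_species < 1 or self.top_k < 1 or self.n_shuffles < 1 \
                or self.n_permutations < 1 or self.min_bbl < 0:
            raise ValueError("parameter out of range")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenResult:
    """Artifacts of one full screen run."""

    conserved: list
    eroded: dict[str, list]
    independent_all: IndependentSet
    independent: IndependentSet          # ranked, deduplicated, classified
    mechanism_counts: dict[str, int]
    enrichment: pd.DataFrame
    significant_terms: pd.DataFrame
    permutation: PermutationResult | None


def build_nulls(pwms, blocks, tree, masks: GenomeMask,
                profile: ConservationProfile, n_shuffles: int = 10,
                seed: int = 0, threshold: float = 0.8) -> dict[str, NullDistribution]:
    """Shuffled-motif null distributions, one per motif, seeded per motif."""
    rng = np.random.default_rng(seed)
    nulls = {}
    for pwm in pwms:
        motif_seed = int(rng.integers(0, 2**31 - 1))
        nulls[pwm.motif_id] = build_null(pwm, blocks, tree, masks, profile,
                                         n_shuffles=n_shuffles,
                                         seed=motif_seed, threshold=threshold,
                                         library=pwms)
        logger.info("null for %s: %d observations",
                    pwm.motif_id, nulls[pwm.motif_id].n_total)
    return nulls


def run_screen(tree, blocks, pwms, masks: GenomeMask,
               outgroups: dict[str, tuple[str, ...]],
               genes=None, terms=None,
               features: dict[str, IntervalSet] | None = None,
               params: ScreenParams | None = None, seed: int = 0,
               target_gaps: dict[str, dict[str, IntervalSet]] | None = None
               ) -> ScreenResult:
    """Run the whole screen.

    ``outgroups`` maps each target species to its outgroup species.  The
    enrichment stage runs when ``genes`` and ``terms`` are given; the
    permutation overlap test when ``features`` is given.
    """
    params = params or ScreenParams()
    params.validate()
    chrom_sizes = dict(masks.chrom_sizes)

    logger.info("conservation profile over %d blocks", len(blocks))
    profile = build_conservation_profile(blocks, tree, chrom_sizes,
                                         window=params.smoothing_window)
    nulls = build_nulls(pwms, blocks, tree, masks, profile,
                        n_shuffles=params.n_shuffles, seed=seed,
                        threshold=params.match_threshold)
    conserved = predict_sites(blocks, tree, pwms, masks, profile, nulls,
                              threshold=params.match_threshold,
                              p_max=params.p_max,
                              min_species=params.min_species,
                              min_bbl=params.min_bbl,
                              null_min_count=params.null_min_count)
    logger.info("conserved sites: %d", len(conserved))

    eroded = {}
    for target, outs in outgroups.items():
        spec = OutgroupSpec(target=target, outgroups=frozenset(outs))
        gaps = (target_gaps or {}).get(target)
        eroded[target] = call_eroded(conserved, spec, blocks, tree,
                                     target_gaps=gaps)
        logger.info("eroded in %s: %d", target, len(eroded[target]))

    targets = list(outgroups)
    ind_all = intersect_independent([eroded[t] for t in targets], targets)
    ind = rank_top_k(ind_all, k=params.top_k)
    ind = dedup_overlaps(ind)
    ind = classify_all(ind, blocks)
    mech = mechanism_table(ind)
    logger.info("independent set: %d (raw %d); mechanisms %s",
                len(ind), len(ind_all), mech)

    regions = [(s.chrom, s.start, s.end) for s in ind.sites]
    if genes is not None and terms is not None and regions:
        enrichment = enrich_terms(regions, genes, terms, chrom_sizes,
                                  basal_up=params.basal_up,
                                  basal_down=params.basal_down,
                                  max_extension=params.max_extension,
                                  min_term_genes=params.min_term_genes,
                                  max_term_genes=params.max_term_genes)
        significant = rank_terms(enrichment, fold_min=params.fold_min,
                                 q_max=params.q_max)
    else:
        enrichment = pd.DataFrame()
        significant = pd.DataFrame()

    permutation = None
    if features is not None and regions:
        allowed = {c: masks.allowed_space(c) for c in chrom_sizes}
        permutation = permutation_overlap_test(
            regions, features, allowed, m=params.n_permutations,
            seed=seed + 1)

    return ScreenResult(conserved=conserved, eroded=eroded,
                        independent_all=ind_all, independent=ind,
                        mechanism_counts=mech, enrichment=enrichment,
                        significant_terms=significant, permutation=permutation)
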