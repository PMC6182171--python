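"""The full independent-erosion screen, end to end, on the default world.

Two target lineages (t1, t2) have eroded a subset of deeply conserved
binding sites that cluster near the genes of one ontology term — the
scenario in which a trait encoded by conserved regulatory sites was lost
independently in two clades.  The screen recovers the eroded sites,
classifies the erosion mechanism (motif mismatch vs deletion), and asks
which ontology term the top-ranked sites share.
"""

from erodescan.pipeline import run_screen
from erodescan.synthetic import WorldConfig, evaluate_recovery, generate_world

world = generate_world(WorldConfig(seed=0))
result = run_screen(world.tree, world.blocks, world.motifs, world.masks,
                    world.outgroups, genes=world.genes, terms=world.terms,
                    features=world.features, seed=0)
report = evaluate_recovery(result.independent, result.enrichment,
                           world.truth, world.trait_term,
                           world.config.targets)

print(f"conserved sites:            {len(result.conserved)}")
for target, eroded in result.eroded.items():
    print(f"eroded in {target}:               {len(eroded)}")
print(f"independently eroded:       {len(result.independent)} "
      f"(raw intersection {len(result.independent_all)})")
print(f"mechanisms:                 {result.mechanism_counts}")
print()
top = result.enrichment.iloc[0]
print(f"top enriched term:          {top['term_id']} "
      f"(fold {top['fold']:.2f}, region q {top['region_q']:.2e}, "
      f"gene q {top['gene_q']:.2e})")
print(f"planted trait term rank:    {report.trait_term_rank} of "
      f"{len(result.enrichment)} terms tested")
print(f"planted-site recall:        {report.recall_independent:.2f}")
perm = result.permutation
print(f"feature overlap:            {perm.observed} of "
      f"{len(result.independent)} sites, fold {perm.fold:.1f}, "
      f"p = {perm.p_value:.3g} ({perm.m} permutations)")
print()
print("The trait term ranking first, with fold >= 2 and both FDRs <= 0.05,")
print("is the screen's positive result: the independently eroded sites")
print("share a biological function.")
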