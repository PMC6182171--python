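import pytest

from erodescan.phylo import parse_newick
from erodescan.pipeline import run_screen
from erodescan.synthetic import WorldConfig, generate_world, evaluate_recovery


@pytest.fixture(scope="session")
def tree3():
    return parse_newick("((A:0.1,B:0.2):0.3,C:0.4);")


def small_config(seed: int = 0) -> WorldConfig:
    """A scaled-down world for fast structural tests."""
    return WorldConfig(
        seed=seed, genome_length=150_000, block_size=50_000,
        n_genes=20, n_terms=5, trait_term_size=10, term_size_range=(10, 12),
        n_exons=6, n_repeats=10, n_conserved=8, n_eroded_single=5,
        n_independent=8, n_background_features=10)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_config())


@pytest.fixture(scope="session")
def small_screen(small_world):
    w = small_world
    return run_screen(w.tree, w.blocks, w.motifs, w.masks, w.outgroups,
                      genes=w.genes, terms=w.terms, features=w.features,
                      seed=0)


def run_default_seed(seed: int):
    """Full screen + recovery report on the default world at ``seed``."""
    w = generate_world(WorldConfig(seed=seed))
    res = run_screen(w.tree, w.blocks, w.motifs, w.masks, w.outgroups,
                     genes=w.genes, terms=w.terms, features=w.features,
                     seed=seed)
    rep = evaluate_recovery(res.independent, res.enrichment, w.truth,
                            w.trait_term, w.config.targets)
    return w, res, rep


@pytest.fixture(scope="session")
def default_run():
    """One screen on the default world (its default seed)."""
    return run_default_seed(WorldConfig().seed)


@pytest.fixture(scope="session")
def multi_seed_runs(default_run):
    """Twenty independent worlds/screens, seeds 0–19 (seed 0 reused)."""
    runs = {WorldConfig().seed: default_run}
    for seed in range(20):
        if seed not in runs:
            runs[seed] = run_default_seed(seed)
    return [runs[s] for s in range(20)]
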