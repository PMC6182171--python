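"""Miniature comparative-genomics world with planted erosion ground truth.

The generator emulates the scenario the screen is built for: a mammalian-like
phylogeny with two (optionally three) target lineages, each with outgroups;
a neutral background alignment produced by Jukes–Cantor substitutions along
the tree; planted binding sites that are exact motif consensus in every
species except where erosion is planted (two disrupting substitutions for a
*mismatch*, a whole-site gap for a *deletion*); and a toy ontology in which
independently eroded sites concentrate inside the regulatory domains of one
"trait" term's genes.  Every artifact is a deterministic function of the
seed, and a truth table records what was planted where.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment import AlignmentBlock, write_maf
from .enrichment import GeneModel, build_domains
from .masks import GenomeMask, IntervalSet
from .motifs import PWM, write_jaspar
from .phylo import PhyloTree, parse_newick

__all__ = ["WorldConfig", "World", "generate_world", "evaluate_recovery",
           "RecoveryReport", "DEFAULT_TREE", "DEFAULT_OUTGROUPS"]

REF_SPECIES = "hg"

# 14-leaf tree: reference clade, two deeply separated target clades (t1, t2)
# with dedicated outgroups, a third optional target clade (t3), and assorted
# background lineages.  Branch lengths in substitutions/site; the total is
# large enough that a site matched everywhere except the targets still spans
# > 3 substitutions/site.
DEFAULT_TREE = (
    "(((((hg:0.16,m1:0.19):0.09,(t1:0.26,(o1a:0.16,o1b:0.17):0.07):0.11):0.08,"
    "((t2:0.27,(o2a:0.15,o2b:0.16):0.08):0.12,m2:0.33):0.07):0.06,"
    "((t3:0.28,o3a:0.22):0.10,m3:0.36):0.08):0.05,"
    "(m4:0.31,m5:0.34):0.10);"
)

DEFAULT_OUTGROUPS: dict[str, tuple[str, ...]] = {
    "t1": ("o1a", "o1b"),
    "t2": ("o2a", "o2b"),
    "t3": ("o3a",),
}

# Fixed motif library: width-8 motifs with 0.85/0.05 column frequencies.
# M3 carries a CpG dinucleotide to exercise CpG-preserving shuffles.  The
# consensi use self-complementary but pairwise distinct base compositions
# (A2C2G2T2, A3C1G1T3, A1C3G3T1), so a column shuffle of one motif — or of
# its reverse complement — can agree with a *different* motif's consensus
# in at most 6 of 8 positions (MATCH 0.75 < 0.8): shuffled-motif nulls
# cannot be contaminated by planted sites of the other motifs.
MOTIF_CONSENSUS = {"M1": "GATCAGTC", "M2": "ATTAGCAT", "M3": "GCCGTAGC"}

CATEGORIES = ("conserved", "eroded_single", "independent")


def _consensus_pwm(motif_id: str, consensus: str, major: float = 0.85) -> PWM:
    minor = (1.0 - major) / 3.0
    idx = {b: i for i, b in enumerate("ACGT")}
    m = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = major
    return PWM.from_counts(motif_id, m, pseudocount=0.0)


@dataclass
class WorldConfig:
    """Study conditions for the synthetic world."""

    seed: int = 0
    chrom: str = "chr1"
    genome_length: int = 1_500_000
    block_size: int = 100_000
    tree_newick: str = DEFAULT_TREE
    targets: tuple[str, ...] = ("t1", "t2")
    n_genes: int = 100
    n_terms: int = 30
    trait_term_size: int = 15
    term_size_range: tuple[int, int] = (10, 20)
    n_exons: int = 40
    exon_length: tuple[int, int] = (400, 800)
    n_repeats: int = 80
    repeat_length: tuple[int, int] = (300, 1200)
    n_conserved: int = 60
    n_eroded_single: int = 25          # per target lineage
    n_independent: int = 40
    trait_placement_prob: float = 0.9  # independent sites inside trait domains
    mechanism_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    single_deletion_prob: float = 0.3
    feature_site_prob: float = 0.85
    n_background_features: int = 60
    feature_halfwidth: int = 200
    min_site_spacing: int = 150
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000

    def __post_init__(self) -> None:
        if abs(sum(self.mechanism_mix)) > 1 + 1e-9:
            raise ValueError("mechanism mix fractions must sum to <= 1")
        lo, hi = self.term_size_range
        if not 10 <= self.trait_term_size <= 500:
            raise ValueError("trait term size must lie in [10, 500]")
        if len(self.targets) not in (2, 3):
            raise ValueError("two or three target lineages are supported")


@dataclass
class World:
    """All inputs the screen consumes, plus the planted ground truth."""

    config: WorldConfig
    tree: PhyloTree
    blocks: list[AlignmentBlock]
    masks: GenomeMask
    motifs: list[PWM]
    genes: list[GeneModel]
    terms: dict[str, list[str]]
    trait_term: str
    outgroups: dict[str, tuple[str, ...]]
    features: dict[str, IntervalSet]
    truth: pd.DataFrame

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.masks.chrom_sizes)

    def write(self, outdir) -> None:
        """Write every artifact as plain text in the formats the pipeline
        reads back (newick, MAF, JASPAR, BED, GMT, TSV)."""
        import os
        import yaml

        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(outdir, name)
        with open(p("tree.nwk"), "w") as fh:
            fh.write(self.tree.newick + "\n")
        with open(p("alignment.maf"), "w") as fh:
            write_maf(fh, self.blocks, order=list(self.tree.leaves))
        with open(p("motifs.jaspar"), "w") as fh:
            write_jaspar(fh, self.motifs)
        chrom = self.config.chrom
        for name, sets in (("exons.bed", self.masks.exons),
                           ("repeats.bed", self.masks.repeats),
                           ("gaps.bed", self.masks.assembly_gaps),
                           ("features.bed", self.features)):
            with open(p(name), "w") as fh:
                ivs = sets.get(chrom)
                if ivs is not None:
                    for s, e in zip(ivs.starts, ivs.ends):
                        fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(p("chrom.sizes"), "w") as fh:
            for c, size in self.chrom_sizes.items():
                fh.write(f"{c}\t{size}\n")
        with open(p("genes.tsv"), "w") as fh:
            fh.write("chrom\ttss\tstrand\tgene_id\n")
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.tss}\t{g.strand}\t{g.gene_id}\n")
        with open(p("ontology.gmt"), "w") as fh:
            for term_id, members in self.terms.items():
                fh.write("\t".join([term_id, term_id] + list(members)) + "\n")
        self.truth.to_csv(p("truth.tsv"), sep="\t", index=False)
        with open(p("outgroups.yaml"), "w") as fh:
            yaml.safe_dump({t: list(o) for t, o in self.outgroups.items()
                            if t in self.config.targets}, fh)


def _jc_substitute(codes: np.ndarray, branch: float, rng) -> np.ndarray:
    """Jukes–Cantor substitutions: P(change) = 3/4 (1 - exp(-4/3 b))."""
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch))
    out = codes.copy()
    hit = rng.random(len(codes)) < p
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _evolve_leaves(newick: str, length: int, rng) -> dict[str, np.ndarray]:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    seqs: dict[int, np.ndarray] = {}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = rng.integers(0, 4, size=length, dtype=np.int8)
        else:
            seqs[id(node)] = _jc_substitute(seqs[id(node.parent_node)],
                                            node.edge.length, rng)
        if node.is_leaf():
            leaves[node.taxon.label] = seqs[id(node)]
    return leaves


def _random_intervals(rng, n: int, length_range: tuple[int, int],
                      genome: int) -> IntervalSet:
    lens = rng.integers(length_range[0], length_range[1] + 1, size=n)
    starts = rng.integers(0, genome - lens.max() - 1, size=n)
    return IntervalSet.from_pairs(zip(starts.tolist(), (starts + lens).tolist()))


def _sample_position(rng, candidate: IntervalSet, width: int, placed: list[int],
                     spacing: int, max_tries: int = 1000) -> int:
    lens = np.maximum(candidate.ends - candidate.starts - width, 0)
    if lens.sum() == 0:
        raise ValueError("infeasible placement: no room in candidate space")
    w = lens / lens.sum()
    for _ in range(max_tries):
        seg = rng.choice(len(lens), p=w)
        pos = int(candidate.starts[seg] + rng.integers(0, lens[seg]))
        if all(abs(pos - q) >= spacing for q in placed):
            return pos
    raise ValueError("infeasible placement density: could not place a site")


def generate_world(config: WorldConfig | None = None) -> World:
    """Generate a deterministic synthetic world from ``config``.

    Same config (incl. seed) ⇒ byte-identical written artifacts.
    """
    cfg = config or WorldConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = parse_newick(cfg.tree_newick)
    for t in cfg.targets:
        if t not in DEFAULT_OUTGROUPS:
            raise ValueError(f"no outgroup specification for target {t!r}")
        tree.leaf_index(t)

    L = cfg.genome_length
    chrom = cfg.chrom
    leaves = _evolve_leaves(cfg.tree_newick, L, rng)

    exons = _random_intervals(rng, cfg.n_exons, cfg.exon_length, L)
    repeats = _random_intervals(rng, cfg.n_repeats, cfg.repeat_length, L)
    masks = GenomeMask(chrom_sizes={chrom: L},
                       exons={chrom: exons}, repeats={chrom: repeats})
    allowed = masks.allowed_space(chrom)

    # genes on a jittered grid; strand-aware basal+extension domains
    spacing = L // cfg.n_genes
    tss = (np.arange(cfg.n_genes) * spacing + spacing // 2
           + rng.integers(-spacing // 4, spacing // 4 + 1, size=cfg.n_genes))
    tss = np.clip(tss, 0, L - 1)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = [GeneModel(f"G{i:03d}", chrom, int(t), s)
             for i, (t, s) in enumerate(zip(tss, strands))]
    domains = build_domains(genes, {chrom: L}, cfg.basal_up, cfg.basal_down,
                            cfg.max_extension)
    dom_by_gene = {d.gene_id: d for d in domains}

    # ontology: one trait term plus random terms
    gene_ids = [g.gene_id for g in genes]
    trait_genes = sorted(rng.choice(gene_ids, size=cfg.trait_term_size,
                                    replace=False).tolist())
    terms: dict[str, list[str]] = {"term_trait": trait_genes}
    for i in range(cfg.n_terms - 1):
        size = int(rng.integers(cfg.term_size_range[0],
                                cfg.term_size_range[1] + 1))
        terms[f"term{i:03d}"] = sorted(rng.choice(gene_ids, size=size,
                                                  replace=False).tolist())

    trait_space = IntervalSet.from_pairs(
        (dom_by_gene[g].ext_start, dom_by_gene[g].ext_end) for g in trait_genes)
    # placements must fall in allowed space; trait placements also in trait domains
    trait_allowed = _intersect(trait_space, allowed)

    motifs = [_consensus_pwm(mid, cons) for mid, cons in MOTIF_CONSENSUS.items()]
    base_index = {b: i for i, b in enumerate("ACGT")}

    placed: list[int] = []
    records: list[dict] = []

    def plant(category: str, k: int, target_mechs: dict[str, str], in_trait: bool):
        pos = _sample_position(rng,
                               trait_allowed if in_trait else allowed,
                               motifs[0].width + 2, placed, cfg.min_site_spacing)
        placed.append(pos)
        pwm = motifs[k % len(motifs)]
        strand = "+" if rng.random() < 0.5 else "-"
        records.append({"chrom": chrom, "start": pos, "end": pos + pwm.width,
                        "strand": strand, "motif_id": pwm.motif_id,
                        "category": category, "in_trait_domain": in_trait,
                        **{f"mech_{t}": target_mechs.get(t, "")
                           for t in cfg.targets}})

    for k in range(cfg.n_conserved):
        plant("conserved", k, {}, False)
    for t in cfg.targets:
        for k in range(cfg.n_eroded_single):
            mech = "deletion" if rng.random() < cfg.single_deletion_prob else "mismatch"
            plant(f"eroded_{t}_only", k, {t: mech}, False)
    p_mm, p_mixed, p_del = cfg.mechanism_mix
    for k in range(cfg.n_independent):
        u = rng.random()
        if u < p_mm:
            mechs = {t: "mismatch" for t in cfg.targets}
        elif u < p_mm + p_mixed:
            deleted = cfg.targets[int(rng.integers(0, len(cfg.targets)))]
            mechs = {t: ("deletion" if t == deleted else "mismatch")
                     for t in cfg.targets}
        else:
            mechs = {t: "deletion" for t in cfg.targets}
        plant("independent", k, mechs, bool(rng.random() < cfg.trait_placement_prob))

    truth = pd.DataFrame.from_records(records).sort_values(
        ["start"]).reset_index(drop=True)

    # write planted sites into the leaf sequences
    pwm_by_id = {p.motif_id: p for p in motifs}
    deletions: dict[str, list[tuple[int, int]]] = {sp: [] for sp in tree.leaves}
    from .alignment import revcomp as _rc
    for rec in truth.itertuples():
        pwm = pwm_by_id[rec.motif_id]
        cons = MOTIF_CONSENSUS[rec.motif_id]
        pattern = cons if rec.strand == "+" else _rc(cons)
        pat = np.array([base_index[b] for b in pattern], dtype=np.int8)
        for sp in tree.leaves:
            leaves[sp][rec.start:rec.end] = pat
        for t in cfg.targets:
            mech = getattr(rec, f"mech_{t}")
            if mech == "mismatch":
                # two substitutions, enough to sink MATCH below 0.8
                for col in (2, 5):
                    leaves[t][rec.start + col] = (pat[col] + 1) % 4
            elif mech == "deletion":
                deletions[t].append((rec.start, rec.end))

    # regulatory-feature track: windows around most independent sites
    feat_pairs: list[tuple[int, int]] = []
    hw = cfg.feature_halfwidth
    for rec in truth[truth["category"] == "independent"].itertuples():
        if rng.random() < cfg.feature_site_prob:
            feat_pairs.append((max(0, rec.start - hw), min(L, rec.end + hw)))
    for _ in range(cfg.n_background_features):
        s = int(rng.integers(0, L - 2 * hw))
        feat_pairs.append((s, s + 2 * hw))
    features = {chrom: IntervalSet.from_pairs(feat_pairs)}

    blocks = _build_blocks(cfg, tree, leaves, deletions)
    return World(config=cfg, tree=tree, blocks=blocks, masks=masks,
                 motifs=motifs, genes=genes, terms=terms,
                 trait_term="term_trait",
                 outgroups={t: DEFAULT_OUTGROUPS[t] for t in cfg.targets},
                 features=features, truth=truth)


def _intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    pairs = []
    for s, e in zip(a.starts.tolist(), a.ends.tolist()):
        i = np.searchsorted(b.ends, s, side="right")
        while i < len(b.starts) and b.starts[i] < e:
            pairs.append((max(s, int(b.starts[i])), min(e, int(b.ends[i]))))
            i += 1
    return IntervalSet.from_pairs(pairs)


def _build_blocks(cfg: WorldConfig, tree: PhyloTree,
                  leaves: dict[str, np.ndarray],
                  deletions: dict[str, list[tuple[int, int]]]) -> list[AlignmentBlock]:
    decode = np.array(list("ACGT"))
    gapped: dict[str, np.ndarray] = {}
    for sp in tree.leaves:
        chars = decode[leaves[sp]].copy()
        for s, e in deletions.get(sp, ()):
            chars[s:e] = "-"
        gapped[sp] = chars
    blocks = []
    for start in range(0, cfg.genome_length, cfg.block_size):
        end = min(start + cfg.block_size, cfg.genome_length)
        rows = {sp: "".join(gapped[sp][start:end]) for sp in tree.leaves}
        blocks.append(AlignmentBlock(
            ref_species=REF_SPECIES, ref_chrom=cfg.chrom, ref_start=start,
            rows=rows, src_sizes={sp: cfg.genome_length for sp in tree.leaves}))
    return blocks


def null_term_pvalues(seed: int, n_regions: int = 300, n_genes: int = 100,
                      n_terms: int = 30, genome_length: int = 1_500_000,
                      term_size_range: tuple[int, int] = (10, 20),
                      region_width: int = 8, chrom: str = "chr1") -> np.ndarray:
    """Binomial region-test P-values for a signal-free world.

    Genes, terms and regions are drawn exactly as in the world generator but
    without any planted signal: region midpoints are uniform over the
    genome, so each term's hit count is Binomial(n, genome fraction) and the
    returned P-values should be (sub)uniform.  Used to check the calibration
    of the region-based test.
    """
    from .enrichment import (associate_regions, binomial_region_test,
                             term_genome_fraction)

    rng = np.random.default_rng(seed)
    spacing = genome_length // n_genes
    tss = (np.arange(n_genes) * spacing + spacing // 2
           + rng.integers(-spacing // 4, spacing // 4 + 1, size=n_genes))
    tss = np.clip(tss, 0, genome_length - 1)
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = [GeneModel(f"G{i:03d}", chrom, int(t), s)
             for i, (t, s) in enumerate(zip(tss, strands))]
    domains = build_domains(genes, {chrom: genome_length})
    gene_ids = [g.gene_id for g in genes]
    terms = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        terms[f"term{i:03d}"] = set(rng.choice(gene_ids, size=size, replace=False))

    starts = rng.integers(0, genome_length - region_width, size=n_regions)
    regions = [(chrom, int(s), int(s) + region_width) for s in starts]
    assoc = [set(a) for a in associate_regions(regions, domains)]
    pvals = []
    for members in terms.values():
        hits = sum(1 for a in assoc if a & members)
        frac = term_genome_fraction(members, domains, genome_length)
        p, _ = binomial_region_test(n_regions, hits, frac)
        pvals.append(p)
    return np.asarray(pvals)


@dataclass
class RecoveryReport:
    """How well one screen run recovered the planted truth."""

    recall_independent: float
    precision_independent: float
    trait_term_rank: int
    trait_term_fold: float
    trait_term_region_q: float
    trait_term_gene_q: float
    mechanism_confusion: pd.DataFrame
    n_detected_independent: int
    n_truth_independent: int


def evaluate_recovery(ind_set, enrichment_df: pd.DataFrame, truth: pd.DataFrame,
                      trait_term: str, targets: tuple[str, ...]) -> RecoveryReport:
    """Score a screen run against the planted truth.

    Detected and planted independently eroded sites are matched by exact
    reference interval.  The trait-term rank is its 1-based position in the
    enrichment table (sorted by region q, then binomial P).
    """
    truth_ind = truth[truth["category"] == "independent"]
    truth_keys = set(zip(truth_ind["start"], truth_ind["end"]))
    det_keys = set((s.start, s.end) for s in ind_set.sites)
    tp = truth_keys & det_keys
    recall = len(tp) / len(truth_keys) if truth_keys else float("nan")
    precision = len(tp) / len(det_keys) if det_keys else float("nan")

    if trait_term in set(enrichment_df.get("term_id", [])):
        row = enrichment_df[enrichment_df["term_id"] == trait_term].iloc[0]
        rank = int(enrichment_df.index[enrichment_df["term_id"] == trait_term][0]) + 1
        fold, rq, gq = float(row["fold"]), float(row["region_q"]), float(row["gene_q"])
    else:
        rank, fold, rq, gq = -1, float("nan"), float("nan"), float("nan")

    # per-target mechanism confusion over matched sites
    truth_by_key = {(r.start, r.end): r for r in truth_ind.itertuples()}
    site_by_key = {(s.start, s.end): s for s in ind_set.sites}
    rows = []
    for key in sorted(tp):
        trec = truth_by_key[key]
        mechs = ind_set.mechanisms.get(site_by_key[key].key, {})
        for t in targets:
            rows.append({"target": t, "truth": getattr(trec, f"mech_{t}"),
                         "called": mechs.get(t, "")})
    confusion = (pd.DataFrame(rows).groupby(["truth", "called"]).size()
                 .unstack(fill_value=0) if rows else pd.DataFrame())

    return RecoveryReport(
        recall_independent=recall, precision_independent=precision,
        trait_term_rank=rank, trait_term_fold=fold,
        trait_term_region_q=rq, trait_term_gene_q=gq,
        mechanism_confusion=confusion,
        n_detected_independent=len(det_keys),
        n_truth_independent=len(truth_keys))
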