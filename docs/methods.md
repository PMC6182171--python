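# Methods

This note records the model choices, parameter conventions and numerical
decisions behind `erodescan`, and what the synthetic-world tests do and do
not establish.

## Conservation model

The per-base conservation statistic is a branch-length-weighted percent
identity.  For a reference base, let *S* be the species whose aligned base
equals the reference base (case-insensitive; `N`, gaps and absent species
count as non-matching).  The statistic is the branch length of the minimal
(Steiner) subtree of the phylogeny spanning *S* ∪ {reference}, divided by
the total branch length *T*, so PID ∈ [0, 1] with PID = 1 exactly when
every species in the tree aligns and matches.  An edge belongs to the
spanning subtree iff it separates two members of the set; this is computed
for whole alignment columns at once from precomputed per-edge leaf sets.

Profiles are smoothed with a centered moving average (default window
100 bp; even windows cover `[i−w/2+1, i+w/2]`), truncated — not mirrored —
at block edges: truncation is unbiased for stationary backgrounds and does
not manufacture conservation at boundaries.  Smoothed values are binned at
1% resolution (`floor(100·pid)`, clamped to 99).

The same subtree-length primitive, applied to the species whose aligned
sequence matches a motif (MATCH ≥ 0.8), is the site's BBL score.  It is a
deterministic surrogate for a Bayesian branch-length score: monotone in the
matched species set, zero for fewer than two species, equal to *T* when all
species match.

## MATCH scoring

Motif similarity is the information-weighted, min–max-normalised sum of
column frequencies (log base 2; the base cancels in the normalised score).
Conventions: pseudocount 0.001 added per cell after count normalisation
(zero-count columns become uniform); windows containing `N` never match;
a degenerate motif with S_max = S_min scores 0.  Only the full-matrix score
is used; no separate core-similarity stage.  Scanning is strand-symmetric:
the reverse strand is scored with the reverse-complement matrix at the same
forward offsets.

## The shuffled-motif null and its validity

The excess-conservation test compares a site's BBL with BBL scores of
column-shuffled motifs matched in the same 1% conservation bin.  Shuffles
permute columns uniformly, with annotated CpG column pairs moving as intact
C→G units (CpG pairs are auto-detected from the consensus, overridable).

Two rules keep the null a *background* model:

- **Null resolution.**  The empirical P is (b+1)/(N+1), so P ≤ 10⁻³ is
  only attainable once a bin holds ≥ 999 null observations.  Sparse bins
  borrow: a query pools bins outward by distance until at least 1,000
  observations are available.  The default of 30 shuffles per motif keeps
  the per-bin floor several-fold below the 10⁻³ gate at megabase scan
  scales, so a single extreme null cannot blank out an entire bin.
- **Null validity.**  A shuffle whose column order (nearly) reproduces the
  original motif — or its reverse complement, or another same-width motif
  of the scanned library — does not probe background: it re-scans real
  sites.  "Nearly" means at most one differing column at offsets 0/±1 and
  none at ±2, which is exactly the set of orderings that still score real
  instances above the 0.8 threshold.  Such draws are rejected and
  resampled; motifs with no informative shuffle (e.g. all-identical
  columns) raise an error rather than loop.

## Filter gates and ranking

A conserved site must have empirical P ≤ 10⁻³, be matched in at least five
species (the reference itself counts, and must match for the window to be
evaluated at all), and span at least 3.0 substitutions/site of matching
branch length.  Overlapping same-locus hits on both strands are both kept
at this stage; overlap resolution happens after the lineage intersection.
A site's conservation bin is that of the window's central base
(`start + width//2`).

Erosion calls require the target absent from the matching set and at least
one declared outgroup present; the target rows over the site must contain
no `N`, and an optional per-target assembly-gap BED (in reference
coordinates) discards further calls.  The independent set is ranked by
empirical P ascending with ties broken by higher BBL, then leftmost
coordinate; the top-k cut (default 5,000) keeps every site tied with the
k-th P-value, so no arbitrary tie-breaking occurs at the boundary.  Dedup
is greedy highest-rank-first, strand-agnostic, on half-open intervals.
Mechanism classification is per target: *mismatch* if at least one target
base aligns across the site's columns, else *deletion*.

## Enrichment

Regulatory domains follow the basal-plus-extension rule: basal 5 kb
upstream / 1 kb downstream of the TSS (strand-aware, clipped to the
chromosome), extended up to 1 Mb per side but stopping at the nearest
neighbouring basal domain, never shrinking below the gene's own basal
region.  A region associates with every gene whose *extended* domain
contains the region midpoint — the midpoint convention makes hits
unambiguous and consistent with the fraction-of-genome success probability
of the region-based binomial test.  The term's genome fraction is the
union coverage of its member domains over the genome length.  The
gene-based test is an upper-tail hypergeometric over the universe of genes
with domains; the term-size filter (10–500 genes, applied after
intersection with the universe) and the significance gates (region fold
≥ 2, both BH FDRs ≤ 0.05, BH across exactly the tested terms) follow the
screen's standard operating point.

The permutation overlap test places length-preserved, mutually
non-overlapping copies of the regions uniformly over the allowed space
(genome minus exons and repeats) and counts regions overlapping ≥ 1
feature; P = (b+1)/(m+1) with m = 10,000 by default, so P is never 0 and
its floor is 1/(m+1).  Placement is joint rejection sampling over all
permutations on a flattened coordinate axis; only permutations with
internal overlaps are redrawn, with a bounded retry count for pathological
densities.

## The synthetic world

The generator emulates the screen's target scenario at desk scale: one
1.5 Mb chromosome, a fixed 14-leaf tree (total branch length 4.37
substitutions/site) containing two deeply separated target clades with
dedicated outgroups and an optional third target clade; background
sequence evolves by Jukes–Cantor substitutions along the branches
(no background indels).  Planted sites are exact consensus in all species,
except in eroding targets: *mismatch* erosion substitutes two columns
(MATCH 0.75 < 0.8), *deletion* erosion gaps the whole target row.  The
default mix is 60% both-mismatch, 30% mixed, 10% both-deletion for the 40
independently eroded sites; 90% of those are placed inside trait-term gene
domains, making the trait term's expected region fold ≈ 4 against a ~15%
genome fraction.  100 genes on a jittered 15 kb grid, 30 ontology terms of
10–20 genes, ~5% of the genome masked as exons/repeats, and a feature
track covering 85% of independent sites plus background intervals complete
the world.  Everything is a deterministic function of the seed, and the
toy motif consensi use self-complementary, pairwise distinct base
compositions so that no shuffle of one motif can collide with another
(see "Null validity").

What passing these tests shows: the statistics are implemented correctly,
the gates enforce what they claim, and under the stated conditions the
screen recovers planted erosion and its shared function with recall
≥ 0.9 and the trait term ranked first in ≥ 90% of worlds.  What it does
not show: performance on real alignments with rate heterogeneity,
context-dependent mutation, alignment error, paralog-rich motif libraries,
or erosion that is partial rather than planted — none of which the world
simulates.

## Problem sizes and numerical conventions

Default test/acceptance runs use the 1.5 Mb world (≈ 14 s per screen on
one CPU), 20 worlds for the multi-seed checks, and 50 signal-free worlds of
300 regions × 30 terms for the calibration of the binomial test (pooled
binomial SE of the attained size).  Empirical-P comparisons use
`searchsorted` on sorted nulls; BH q-values come from statsmodels; binomial
and hypergeometric tails from scipy survival functions (never 1 − CDF).
Coordinates are 0-based half-open throughout; MAF blocks on the reference
minus strand are normalised to the forward strand on input.  Bases compare
case-insensitively (soft-masking is handled only through the repeat mask).

## Known limitations

- The BBL surrogate ignores within-site heterogeneity of the matched
  species sets across columns; a fully Bayesian branch-length score would
  weight partial matches.
- The binomial region test is slightly conservative for small expected hit
  counts (discreteness), visible in the null calibration as attained sizes
  marginally off 0.05.
- Region placement in the permutation test is uniform over allowed space
  and ignores GC or conservation matching of the shuffled regions.
- The GREAT-style curated-domain exceptions for special gene classes are
  not implemented.
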