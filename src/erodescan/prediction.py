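"""Conserved binding-site prediction.

A window is a candidate when the reference sequence matches a motif
(MATCH ≥ 0.8) inside the allowed space (no exons, no repeats).  Its
conservation support is the *BBL score*: the branch length of the minimal
subtree spanning the species whose aligned sequence also matches.  Each
candidate is tested against a null of BBL scores from column-shuffled
motifs, stratified by the 1% conservation bin of the window's central base,
giving an empirical excess-conservation P-value.  Retained sites must pass
P ≤ 1e-3, be matched in at least five species, and carry at least 3.0
substitutions/site of matching branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentBlock, ConservationProfile, GAP_CODE, N_CODE
from .masks import GenomeMask
from .motifs import PWM, score_all_offsets, score_windows
from .phylo import PhyloTree

__all__ = [
    "ConservedSite",
    "NullDistribution",
    "site_species_matches",
    "bbl_score",
    "build_null",
    "empirical_p",
    "predict_sites",
]


@dataclass(frozen=True)
class ConservedSite:
    """A conserved motif match on the reference genome."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    matching_species: frozenset[str]
    bbl: float
    conservation_bin: int
    empirical_p: float

    @property
    def n_species(self) -> int:
        return len(self.matching_species)

    @property
    def key(self) -> tuple:
        """Site identity: interval + motif + strand."""
        return (self.chrom, self.start, self.end, self.strand, self.motif_id)


def bbl_score(tree: PhyloTree, matching) -> float:
    """Branch length of the subtree spanning the matching species.

    Zero when at most one species matches.
    """
    return tree.induced_subtree_length(matching)


def _strand_pwm(pwm: PWM, strand: str) -> PWM:
    if strand == "+":
        return pwm
    if strand == "-":
        return pwm.reverse_complement()
    raise ValueError(f"unknown strand {strand!r}")


def _match_matrix(block: AlignmentBlock, pwm: PWM, offsets: np.ndarray,
                  strand: str, tree: PhyloTree, threshold: float) -> np.ndarray:
    """Boolean (n_offsets, n_leaves): species whose aligned, gapless sequence
    over each window's columns scores MATCH ≥ threshold on ``strand``.

    ``offsets`` index into the block's ungapped reference.
    """
    w = pwm.width
    p = _strand_pwm(pwm, strand)
    match = np.zeros((len(offsets), len(tree.leaves)), dtype=bool)
    if block.ref_length == block.width:  # no reference gaps: columns == positions
        idx = offsets[:, None] + np.arange(w)[None, :]
        for sp in block.species:
            wins = block.encoded(sp)[idx]
            match[:, tree.leaf_index(sp)] = score_windows(p, wins) >= threshold
    else:
        for k, off in enumerate(np.asarray(offsets)):
            start = block.ref_start + int(off)
            for sp in block.species:
                codes = block.species_codes(sp, start, start + w)
                codes = codes[codes != GAP_CODE]
                if len(codes) != w or (codes == N_CODE).any():
                    continue
                if score_windows(p, codes[None, :])[0] >= threshold:
                    match[k, tree.leaf_index(sp)] = True
    return match


def site_species_matches(block: AlignmentBlock, pwm: PWM, ref_offset: int,
                         strand: str, tree: PhyloTree,
                         threshold: float = 0.8) -> frozenset[str]:
    """Species whose aligned sequence at one window matches the motif.

    ``ref_offset`` is relative to the block's ungapped reference row; the
    window must fit inside the block.  A species whose gapless sequence over
    the window's columns is not exactly motif-width long cannot match.
    """
    if ref_offset < 0 or ref_offset + pwm.width > block.ref_length:
        raise ValueError("motif window outside block reference row")
    m = _match_matrix(block, pwm, np.array([ref_offset]), strand, tree, threshold)
    return frozenset(tree.leaves[j] for j in np.flatnonzero(m[0]))


def _candidate_offsets(block: AlignmentBlock, pwm: PWM, strand: str,
                       masks: GenomeMask, threshold: float) -> np.ndarray:
    """Window offsets (into the ungapped reference) where the reference row
    matches and the window lies wholly inside allowed space."""
    ref_codes = block.encoded(block.ref_species)[block.ref_columns]
    scores = score_all_offsets(_strand_pwm(pwm, strand), ref_codes)
    offs = np.flatnonzero(scores >= threshold)
    if len(offs) == 0:
        return offs
    starts = offs + block.ref_start
    allowed = masks.allowed_space(block.ref_chrom)
    keep = allowed.contains_window(starts, starts + pwm.width)
    return offs[keep]


def _window_bins(block: AlignmentBlock, offsets: np.ndarray, width: int,
                 profile: ConservationProfile) -> np.ndarray:
    centers = offsets + block.ref_start + width // 2
    return profile.bins[block.ref_chrom][centers]


@dataclass
class NullDistribution:
    """Per-conservation-bin null BBL scores for one motif.

    Sparse bins borrow: a query pools scores from the nearest bins (by
    distance to the query bin, lower bin first on ties) until at least
    ``min_count`` null observations are available.
    """

    motif_id: str
    by_bin: dict[int, np.ndarray]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_records(cls, motif_id: str, bins: np.ndarray, scores: np.ndarray) -> "NullDistribution":
        by_bin: dict[int, np.ndarray] = {}
        bins = np.asarray(bins)
        scores = np.asarray(scores, dtype=float)
        for b in np.unique(bins):
            by_bin[int(b)] = np.sort(scores[bins == b])
        return cls(motif_id=motif_id, by_bin=by_bin)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.by_bin.values())

    def scores_for_bin(self, cons_bin: int, min_count: int = 1000) -> np.ndarray:
        """Sorted null scores for a conservation bin, pooled outward from the
        query bin until ``min_count`` observations are reached."""
        if not self.by_bin:
            raise ValueError(
                f"null distribution for {self.motif_id} is empty in every bin; "
                "increase the number of shuffles or the scanned sequence")
        key = (cons_bin, min_count)
        if key not in self._cache:
            order = sorted(self.by_bin, key=lambda b: (abs(b - cons_bin), b))
            chunks: list[np.ndarray] = []
            total = 0
            for b in order:
                chunks.append(self.by_bin[b])
                total += len(self.by_bin[b])
                if total >= min_count:
                    break
            self._cache[key] = np.sort(np.concatenate(chunks))
        return self._cache[key]


def empirical_p(score: float, null_scores: np.ndarray) -> float:
    """P(null ≥ score) with the add-one correction: (b + 1) / (N + 1).

    Never exactly zero; 1e-3 is only reachable once a bin holds ≥ 999 nulls.
    """
    null_scores = np.asarray(null_scores)
    if len(null_scores) == 0:
        raise ValueError("empty null distribution bin")
    n_ge = len(null_scores) - int(np.searchsorted(null_scores, score, side="left"))
    return (n_ge + 1) / (len(null_scores) + 1)


def _near_identity(shuffled: np.ndarray, original: np.ndarray,
                   max_shift: int = 2) -> bool:
    """True if the shuffled column order nearly reproduces the original
    motif at a small column offset, on either strand.

    "Nearly" means at most one overlapping column differs at offsets 0/±1,
    or none differs at offset ±2 — exactly the orderings that would still
    scan real instances of the original motif as matches.
    """
    w = len(original)
    rc = original[::-1, ::-1]
    for mat in (original, rc):
        for shift in range(-max_shift, max_shift + 1):
            pairs = [(i, i + shift) for i in range(w) if 0 <= i + shift < w]
            diffs = sum(0 if np.allclose(shuffled[i], mat[j]) else 1
                        for i, j in pairs)
            if diffs <= (1 if abs(shift) <= 1 else 0):
                return True
    return False


def null_shuffles(pwm: PWM, n: int, rng, exclude=None,
                  max_tries: int = 1000) -> list[PWM]:
    """``n`` column-shuffled null motifs for ``pwm``.

    A shuffle whose column order (nearly) reproduces the original motif —
    or its reverse complement, since scanning is strand-symmetric — still
    matches real instances of the motif and is therefore not a null; such
    draws are rejected and resampled.  ``exclude`` may list further motifs
    (typically the whole scanned library) whose near-reproduction also
    disqualifies a draw: a shuffle that collides with another real motif
    scans that motif's sites rather than background.  Motifs whose every
    shuffle is disqualified raise instead of looping.
    """
    from .motifs import shuffle_columns

    screens = [pwm.matrix] + [m.matrix for m in (exclude or ())
                              if m.width == pwm.width]
    out: list[PWM] = []
    tries = 0
    while len(out) < n:
        spwm = shuffle_columns(pwm, int(rng.integers(0, 2**31 - 1)))
        tries += 1
        if any(_near_identity(spwm.matrix, mat) for mat in screens):
            if tries > max_tries:
                raise ValueError(
                    f"motif {pwm.motif_id}: every column shuffle reproduces "
                    "a library motif; no informative null is available")
            continue
        out.append(spwm)
    return out


def build_null(pwm: PWM, blocks, tree: PhyloTree, masks: GenomeMask,
               profile: ConservationProfile, n_shuffles: int = 10,
               seed: int = 0, threshold: float = 0.8,
               library=None) -> NullDistribution:
    """Null BBL distribution from column-shuffled motifs.

    Each shuffle is scanned across the allowed space of all blocks; every
    reference match contributes its BBL score to the conservation bin of the
    window's central base.  Distributions are pooled across shuffles.
    ``library`` (the full motif set being scanned) screens out shuffles that
    collide with a real motif; see :func:`null_shuffles`.
    """
    rng = np.random.default_rng(seed)
    all_bins: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    for spwm in null_shuffles(pwm, n_shuffles, rng, exclude=library):
        for blk in blocks:
            for strand in "+-":
                offs = _candidate_offsets(blk, spwm, strand, masks, threshold)
                if len(offs) == 0:
                    continue
                match = _match_matrix(blk, spwm, offs, strand, tree, threshold)
                all_scores.append(tree.induced_length_batch(match))
                all_bins.append(_window_bins(blk, offs, spwm.width, profile))
    if not all_bins:
        raise ValueError(
            f"no shuffled-motif matches for {pwm.motif_id}; "
            "increase the number of shuffles or the scanned sequence")
    return NullDistribution.from_records(
        pwm.motif_id, np.concatenate(all_bins), np.concatenate(all_scores))


def predict_sites(blocks, tree: PhyloTree, pwms, masks: GenomeMask,
                  profile: ConservationProfile, nulls: dict[str, NullDistribution],
                  threshold: float = 0.8, p_max: float = 1e-3,
                  min_species: int = 5, min_bbl: float = 3.0,
                  null_min_count: int = 1000) -> list[ConservedSite]:
    """Call conserved binding sites over the allowed space.

    A reference-matching window is retained iff its excess-conservation
    empirical P ≤ ``p_max``, it is matched in ≥ ``min_species`` species
    (the reference included) and its BBL is ≥ ``min_bbl`` substitutions/site.
    Both strands are evaluated; overlap resolution is left to the erosion
    stage.
    """
    sites: list[ConservedSite] = []
    for pwm in pwms:
        null = nulls[pwm.motif_id]
        for blk in blocks:
            for strand in "+-":
                offs = _candidate_offsets(blk, pwm, strand, masks, threshold)
                if len(offs) == 0:
                    continue
                match = _match_matrix(blk, pwm, offs, strand, tree, threshold)
                bbls = tree.induced_length_batch(match)
                bins = _window_bins(blk, offs, pwm.width, profile)
                for k in range(len(offs)):
                    n_sp = int(match[k].sum())
                    if n_sp < min_species or bbls[k] < min_bbl:
                        continue
                    p = empirical_p(bbls[k], null.scores_for_bin(int(bins[k]), null_min_count))
                    if p > p_max:
                        continue
                    start = int(offs[k]) + blk.ref_start
                    sites.append(ConservedSite(
                        chrom=blk.ref_chrom, start=start, end=start + pwm.width,
                        strand=strand, motif_id=pwm.motif_id,
                        matching_species=frozenset(
                            tree.leaves[j] for j in np.flatnonzero(match[k])),
                        bbl=float(bbls[k]), conservation_bin=int(bins[k]),
                        empirical_p=float(p)))
    sites.sort(key=lambda s: (s.motif_id, s.chrom, s.start, s.end, s.strand))
    return sites
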