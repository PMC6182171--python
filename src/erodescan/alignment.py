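"""Reference-anchored multiple alignments and per-base conservation.

Alignment blocks are read from MAF (via Biopython), normalised to the
reference forward strand, and scored with a *weighted percent identity*:
for every reference base, the branch length of the minimal subtree spanning
the reference plus all species whose aligned base matches it, divided by the
total branch length of the phylogeny.  Profiles are smoothed with a centered
window and discretised into 1% conservation bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import PhyloTree

__all__ = [
    "AlignmentBlock",
    "ConservationProfile",
    "read_maf",
    "write_maf",
    "per_base_identity",
    "smooth_profile",
    "bin_conservation",
    "build_conservation_profile",
]

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")
# A=0 C=1 G=2 T=3, N/other=4, gap=5
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = 5

GAP_CODE = 5
N_CODE = 4


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignmentBlock:
    """One alignment block, anchored on the reference forward strand.

    ``rows`` maps species name to its gapped sequence; all rows span the same
    number of columns.  ``ref_start`` is the 0-based reference coordinate of
    the first reference base in the block.
    """

    ref_species: str
    ref_chrom: str
    ref_start: int
    rows: dict[str, str]
    src_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.rows.values()}
        if len(widths) != 1:
            raise ValueError("ragged alignment block: rows differ in length")
        if self.ref_species not in self.rows:
            raise ValueError("reference species missing from block")
        self._enc = {sp: encode(s) for sp, s in self.rows.items()}
        ref = self._enc[self.ref_species]
        self._ref_cols = np.flatnonzero(ref != GAP_CODE)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ref_length(self) -> int:
        """Number of reference (non-gap) bases."""
        return len(self._ref_cols)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_length

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.rows)

    def encoded(self, species: str) -> np.ndarray:
        return self._enc[species]

    @property
    def ref_columns(self) -> np.ndarray:
        """Column index of each reference base, in reference order."""
        return self._ref_cols

    def column_span(self, start: int, end: int) -> tuple[int, int]:
        """Columns (half-open) spanned by reference interval [start, end)."""
        if start < self.ref_start or end > self.ref_end or end <= start:
            raise ValueError("reference interval outside block")
        lo = self._ref_cols[start - self.ref_start]
        hi = self._ref_cols[end - 1 - self.ref_start] + 1
        return int(lo), int(hi)

    def species_codes(self, species: str, start: int, end: int) -> np.ndarray:
        """Encoded characters of ``species`` across the columns spanning
        reference interval [start, end); gaps included."""
        lo, hi = self.column_span(start, end)
        if species not in self._enc:
            return np.empty(0, dtype=np.int8)
        return self._enc[species][lo:hi]


def read_maf(handle, ref_species: str | None = None):
    """Iterate :class:`AlignmentBlock` from a MAF stream.

    The first "s" row of each block is the reference; source names follow the
    ``species.chrom`` convention.  Blocks whose reference row is on the minus
    strand are reverse-complemented onto the forward strand.
    """
    for msa in AlignIO.parse(handle, "maf"):
        recs = list(msa)
        if not recs:
            continue
        widths = {len(r.seq) for r in recs}
        if len(widths) != 1:
            raise ValueError("ragged alignment block: rows differ in length")
        ref = recs[0]
        ref_sp, _, ref_chrom = ref.id.partition(".")
        if ref_species is not None and ref_sp != ref_species:
            raise ValueError(f"block anchored on {ref_sp!r}, expected {ref_species!r}")
        strand = ref.annotations["strand"]
        if strand not in (1, -1):
            raise ValueError(f"unknown strand code {strand!r}")
        flip = strand == -1
        rows: dict[str, str] = {}
        src_sizes: dict[str, int] = {}
        for rec in recs:
            sp = rec.id.partition(".")[0]
            seq = str(rec.seq)
            rows[sp] = revcomp(seq) if flip else seq
            src_sizes[sp] = int(rec.annotations["srcSize"])
        start = int(ref.annotations["start"])
        if flip:
            start = src_sizes[ref_sp] - (start + int(ref.annotations["size"]))
        yield AlignmentBlock(ref_species=ref_sp, ref_chrom=ref_chrom,
                             ref_start=start, rows=rows, src_sizes=src_sizes)


def write_maf(handle, blocks, order: list[str] | None = None) -> None:
    """Write blocks as MAF, reference row first."""
    writer_blocks = []
    for blk in blocks:
        names = order if order is not None else sorted(blk.rows)
        names = [blk.ref_species] + [n for n in names if n != blk.ref_species and n in blk.rows]
        recs = []
        for sp in names:
            seq = blk.rows[sp]
            size = sum(1 for c in seq if c != "-")
            chrom = blk.ref_chrom
            rec = SeqRecord(Seq(seq), id=f"{sp}.{chrom}")
            rec.annotations = {
                "start": blk.ref_start if sp == blk.ref_species else 0,
                "size": size,
                "strand": 1,
                "srcSize": blk.src_sizes.get(sp, size),
            }
            recs.append(rec)
        writer_blocks.append(MultipleSeqAlignment(recs))
    AlignIO.write(writer_blocks, handle, "maf")


def per_base_identity(block: AlignmentBlock, tree: PhyloTree) -> np.ndarray:
    """Weighted percent identity of each reference base in ``block``.

    PID = induced-subtree length of {reference} ∪ {species matching the
    reference base} over the total branch length.  'N', gaps and absent
    species count as non-matching, so a base aligned by no other species
    scores 0.
    """
    cols = block.ref_columns
    ref_enc = block.encoded(block.ref_species)[cols]
    n_pos = len(cols)
    match = np.zeros((n_pos, len(tree.leaves)), dtype=bool)
    for sp in block.species:
        j = tree.leaf_index(sp)
        codes = block.encoded(sp)[cols]
        match[:, j] = (codes == ref_enc) & (ref_enc < 4)
    lengths = tree.induced_length_batch(match)
    return lengths / tree.total_branch_length()


def smooth_profile(raw: np.ndarray, window: int = 100) -> np.ndarray:
    """Centered moving average, truncated (not mirrored) at the edges.

    For even windows the window covers ``[i - window//2 + 1, i + window//2]``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if n == 0 or window == 1:
        return raw.copy()
    cs = np.concatenate([[0.0], np.cumsum(raw)])
    i = np.arange(n)
    lo = np.clip(i - (window - 1) // 2, 0, n)
    hi = np.clip(i + window // 2 + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def bin_conservation(smoothed_pid) -> np.ndarray | int:
    """1% conservation bin: floor(pid * 100), clamped to 99."""
    v = np.asarray(smoothed_pid, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("smoothed PID outside [0, 1]")
    bins = np.minimum(np.floor(v * 100).astype(np.int64), 99)
    return bins if bins.ndim else int(bins)


@dataclass
class ConservationProfile:
    """Per-chromosome raw/smoothed PID arrays and 1% bins.

    Positions not covered by any alignment block have PID 0.
    """

    raw: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    bins: dict[str, np.ndarray]

    def bin_at(self, chrom: str, pos: int) -> int:
        return int(self.bins[chrom][pos])


def build_conservation_profile(blocks, tree: PhyloTree, chrom_sizes: dict[str, int],
                               window: int = 100) -> ConservationProfile:
    """Stitch per-block PID into genome-wide smoothed, binned profiles."""
    raw = {c: np.zeros(size) for c, size in chrom_sizes.items()}
    for blk in blocks:
        raw[blk.ref_chrom][blk.ref_start:blk.ref_end] = per_base_identity(blk, tree)
    smoothed = {c: smooth_profile(a, window) for c, a in raw.items()}
    bins = {c: bin_conservation(a) for c, a in smoothed.items()}
    return ConservationProfile(raw=raw, smoothed=smoothed, bins=bins)
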