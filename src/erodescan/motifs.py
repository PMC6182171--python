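"""Position weight matrices and information-weighted MATCH scoring.

The MATCH similarity of a window to a PWM weights each column by its
information content I(i) = sum_b f(i,b) * log2(4 f(i,b)) and min–max
normalises the summed weighted frequencies, giving a score in [0, 1] where
1 is the consensus and 0 the anti-consensus.  Column-shuffled motifs — with
CpG dinucleotide columns kept adjacent — provide the matched null used for
the conservation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "MatchScore",
    "read_motifs",
    "information_weights",
    "match_score",
    "shuffle_columns",
    "scan_window",
    "score_all_offsets",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MatchScore:
    value: float
    strand: str
    offset: int


@dataclass
class PWM:
    """Motif as a (width, 4) column-stochastic frequency matrix.

    ``cpg_pairs`` holds the first index of each annotated CpG column pair;
    those pairs are kept adjacent (C before G) when the matrix is shuffled.
    """

    motif_id: str
    matrix: np.ndarray
    cpg_pairs: tuple[int, ...] = ()
    _weights: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if np.any(m < 0):
            raise ValueError("negative frequency in PWM")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        object.__setattr__(self, "matrix", m)
        pairs = tuple(sorted(self.cpg_pairs))
        for a, b in zip(pairs, pairs[1:]):
            if b - a < 2:
                raise ValueError("overlapping CpG pairs")
        if pairs and (pairs[0] < 0 or pairs[-1] + 1 >= len(m)):
            raise ValueError("CpG pair index out of range")
        object.__setattr__(self, "cpg_pairs", pairs)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    pseudocount: float = 0.001,
                    cpg_pairs: tuple[int, ...] | None = None) -> "PWM":
        """Normalise a count (or frequency) matrix with a pseudocount.

        Each column is scaled to frequencies, ``pseudocount`` is added per
        cell and the column renormalised, so every frequency is > 0.  CpG
        pairs are auto-annotated from the consensus unless given explicitly.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must have shape (width, 4)")
        if np.any(c < 0):
            raise ValueError("negative counts")
        totals = c.sum(axis=1, keepdims=True)
        freq = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), 0.0)
        freq = freq + pseudocount
        freq /= freq.sum(axis=1, keepdims=True)
        pwm = cls(motif_id=motif_id, matrix=freq)
        if cpg_pairs is None:
            cpg_pairs = detect_cpg_pairs(pwm.consensus)
        return replace(pwm, cpg_pairs=tuple(cpg_pairs))

    def weights(self) -> np.ndarray:
        """Per-column lookup table I(i)·f(i, b) padded for N (col 4) and gap
        (col 5) with a large negative value so any ambiguous base sinks the
        window below every threshold."""
        if self._weights is None:
            info = information_weights(self)
            w = np.full((self.width, 6), -1e3)
            w[:, :4] = info[:, None] * self.matrix
            object.__setattr__(self, "_weights", w)
        return self._weights

    def score_bounds(self) -> tuple[float, float]:
        info = information_weights(self)
        smin = float((info * self.matrix.min(axis=1)).sum())
        smax = float((info * self.matrix.max(axis=1)).sum())
        return smin, smax

    def reverse_complement(self) -> "PWM":
        m = self.matrix[::-1, ::-1].copy()
        w = self.width
        pairs = tuple(sorted(w - 2 - i for i in self.cpg_pairs))
        return PWM(motif_id=self.motif_id, matrix=m, cpg_pairs=pairs)


def detect_cpg_pairs(consensus: str) -> tuple[int, ...]:
    """Non-overlapping CpG column pairs, greedily left to right."""
    pairs: list[int] = []
    i = 0
    while i < len(consensus) - 1:
        if consensus[i] == "C" and consensus[i + 1] == "G":
            pairs.append(i)
            i += 2
        else:
            i += 1
    return tuple(pairs)


def information_weights(pwm: PWM) -> np.ndarray:
    """I(i) = sum_b f(i,b) log2(4 f(i,b)), with 0·log 0 = 0; in [0, 2]."""
    f = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(4 * np.where(f > 0, f, 1.0)), 0.0)
    return terms.sum(axis=1)


def match_score(pwm: PWM, seq: str) -> float:
    """MATCH similarity of ``seq`` (len = motif width) to the PWM, in [0,1].

    Windows containing 'N' (or any non-ACGT character) score 0.
    """
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {pwm.width}")
    seq = seq.upper()
    info = information_weights(pwm)
    s = 0.0
    for i, ch in enumerate(seq):
        b = _BASE_INDEX.get(ch)
        if b is None:
            return 0.0
        s += info[i] * pwm.matrix[i, b]
    smin, smax = pwm.score_bounds()
    if smax - smin <= 0:
        return 0.0
    return (s - smin) / (smax - smin)


def score_all_offsets(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """MATCH score of every window start in an encoded sequence.

    ``codes`` uses the package base encoding (A=0..T=3, N=4, gap=5); windows
    touching N or gaps score below 0 and can never pass a threshold.
    Returns an array of length ``len(codes) - width + 1``.
    """
    w = pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    weights = pwm.weights()
    s = np.zeros(n)
    for i in range(w):
        s += weights[i, codes[i:i + n]]
    smin, smax = pwm.score_bounds()
    if smax - smin <= 0:
        return np.zeros(n)
    return (s - smin) / (smax - smin)


def score_windows(pwm: PWM, windows: np.ndarray) -> np.ndarray:
    """MATCH scores for an ``(n, width)`` array of encoded windows."""
    weights = pwm.weights()
    s = weights[np.arange(pwm.width)[None, :], windows.astype(np.int64)].sum(axis=1)
    smin, smax = pwm.score_bounds()
    if smax - smin <= 0:
        return np.zeros(len(windows))
    return (s - smin) / (smax - smin)


def shuffle_columns(pwm: PWM, rng_seed) -> PWM:
    """Shuffled-column null motif.

    Columns are permuted uniformly at random, except that each annotated CpG
    pair moves as one unit, staying adjacent and in C→G order.  The column
    multiset is preserved.
    """
    rng = np.random.default_rng(rng_seed)
    units: list[list[int]] = []
    paired = set()
    for i in pwm.cpg_pairs:
        paired.update((i, i + 1))
    i = 0
    while i < pwm.width:
        if i in pwm.cpg_pairs:
            units.append([i, i + 1])
            i += 2
        elif i in paired:  # defensive; pairs are non-overlapping
            i += 1
        else:
            units.append([i])
            i += 1
    order = rng.permutation(len(units))
    cols: list[int] = []
    new_pairs: list[int] = []
    for u in order:
        unit = units[u]
        if len(unit) == 2:
            new_pairs.append(len(cols))
        cols.extend(unit)
    return PWM(motif_id=f"{pwm.motif_id}|shuffled",
               matrix=pwm.matrix[cols].copy(),
               cpg_pairs=tuple(new_pairs))


def scan_window(pwm: PWM, seq: str, threshold: float = 0.8) -> list[MatchScore]:
    """All motif matches (score ≥ threshold) on both strands of ``seq``.

    Reverse-strand hits are scored on the reverse complement and reported at
    their forward-strand offset.
    """
    from .alignment import encode  # local import to avoid cycle

    codes = encode(seq.upper())
    hits: list[MatchScore] = []
    fwd = score_all_offsets(pwm, codes)
    for off in np.flatnonzero(fwd >= threshold):
        hits.append(MatchScore(float(fwd[off]), "+", int(off)))
    rc = pwm.reverse_complement()
    rev = score_all_offsets(rc, codes)
    for off in np.flatnonzero(rev >= threshold):
        hits.append(MatchScore(float(rev[off]), "-", int(off)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def read_motifs(handle, dialect: str = "jaspar", pseudocount: float = 0.001) -> list[PWM]:
    """Read a motif library in JASPAR (4-row) or TRANSFAC format.

    Counts are normalised with :meth:`PWM.from_counts`; CpG pairs are
    auto-annotated from the consensus.
    """
    dialect = dialect.lower()
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown motif dialect {dialect!r}")
    parsed = bio_motifs.parse(handle, dialect)
    out: list[PWM] = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        mid = getattr(m, "matrix_id", None) or m.name or f"motif{len(out) + 1}"
        out.append(PWM.from_counts(str(mid), counts, pseudocount=pseudocount))
    return out


def write_jaspar(handle, pwms: list[PWM], scale: int = 100) -> None:
    """Write motifs as JASPAR count blocks (frequencies × scale)."""
    for pwm in pwms:
        handle.write(f">{pwm.motif_id} {pwm.motif_id}\n")
        for b in BASES:
            row = pwm.matrix[:, _BASE_INDEX[b]] * scale
            vals = " ".join(f"{v:.2f}" for v in row)
            handle.write(f"{b} [ {vals} ]\n")


def score_reverse_offsets(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Reverse-strand MATCH score for every forward window start."""
    return score_all_offsets(pwm.reverse_complement(), codes)
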