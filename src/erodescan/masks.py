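"""Genomic interval masks (exons, repeats, assembly gaps, allowed space).

All coordinates are 0-based half-open.  Interval sets are stored per
chromosome as sorted, merged ``(starts, ends)`` arrays, which keeps point and
window queries to a pair of ``searchsorted`` calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntervalSet", "GenomeMask", "read_bed3", "read_chrom_sizes"]


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class IntervalSet:
    """Sorted, merged intervals on one chromosome."""

    starts: np.ndarray
    ends: np.ndarray

    @classmethod
    def from_pairs(cls, pairs) -> "IntervalSet":
        pairs = list(pairs)
        if not pairs:
            return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        s = np.asarray([p[0] for p in pairs], dtype=np.int64)
        e = np.asarray([p[1] for p in pairs], dtype=np.int64)
        if np.any(e < s):
            raise ValueError("interval end before start")
        return cls(*_merge(s, e))

    def __len__(self) -> int:
        return len(self.starts)

    def total_length(self) -> int:
        return int((self.ends - self.starts).sum())

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval."""
        i = np.searchsorted(self.ends, start, side="right")
        return i < len(self.starts) and self.starts[i] < end

    def overlaps_batch(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.ends, starts, side="right")
        hit = i < len(self.starts)
        hit[hit] &= self.starts[i[hit]] < ends[hit]
        return hit

    def contains_window(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """For each window, True iff it lies wholly inside one interval."""
        i = np.searchsorted(self.starts, starts, side="right") - 1
        ok = i >= 0
        ok[ok] &= ends[ok] <= self.ends[i[ok]]
        return ok

    def complement(self, chrom_size: int) -> "IntervalSet":
        s = np.concatenate([[0], self.ends])
        e = np.concatenate([self.starts, [chrom_size]])
        keep = e > s
        return IntervalSet(s[keep].astype(np.int64), e[keep].astype(np.int64))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(*_merge(np.concatenate([self.starts, other.starts]),
                                   np.concatenate([self.ends, other.ends])))


@dataclass
class GenomeMask:
    """Named interval sets per chromosome plus chromosome sizes.

    ``allowed_space`` — the regions scanned for binding sites and used for
    permutation shuffling — is the complement of exons and repeats.
    """

    chrom_sizes: dict[str, int]
    exons: dict[str, IntervalSet] = field(default_factory=dict)
    repeats: dict[str, IntervalSet] = field(default_factory=dict)
    assembly_gaps: dict[str, IntervalSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = IntervalSet.from_pairs([])
        for sets in (self.exons, self.repeats, self.assembly_gaps):
            for chrom, ivs in sets.items():
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"mask on unknown chromosome {chrom!r}")
                if len(ivs) and ivs.ends[-1] > self.chrom_sizes[chrom]:
                    raise ValueError(f"mask interval beyond end of {chrom}")
        self._allowed = {
            chrom: self.exons.get(chrom, empty)
            .union(self.repeats.get(chrom, empty))
            .complement(size)
            for chrom, size in self.chrom_sizes.items()
        }

    def allowed_space(self, chrom: str) -> IntervalSet:
        return self._allowed[chrom]

    def allowed_total_length(self) -> int:
        return sum(ivs.total_length() for ivs in self._allowed.values())

    def gap_set(self, chrom: str) -> IntervalSet:
        return self.assembly_gaps.get(chrom, IntervalSet.from_pairs([]))


def read_bed3(path) -> dict[str, IntervalSet]:
    """Read a BED3 file into per-chromosome interval sets."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#")
    out: dict[str, IntervalSet] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = IntervalSet.from_pairs(zip(sub["start"], sub["end"]))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(r.chrom): int(r.size) for r in df.itertuples()}
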