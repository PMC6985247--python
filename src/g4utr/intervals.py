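"""Light-weight half-open genomic interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)``. An :class:`IntervalSet`
stores the merged union of its input intervals as two sorted numpy arrays,
which makes point membership a ``searchsorted`` and set algebra a linear sweep.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, non-overlapping, non-adjacent merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class IntervalSet:
    """Merged union of half-open intervals on one sequence/chromosome."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        merged = merge_intervals(intervals)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def total_length(self) -> int:
        return int((self.ends - self.starts).sum())

    def contains_points(self, pos: Sequence[int] | np.ndarray) -> np.ndarray:
        """Boolean array: is each position inside the set?"""
        pos = np.asarray(pos, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] < self.ends[idx[ok]]
        return res

    def overlaps(self, start: int, end: int) -> bool:
        """Does [start, end) intersect any interval in the set?"""
        if end <= start or len(self.starts) == 0:
            return False
        i = int(np.searchsorted(self.ends, start, side="right"))
        return i < len(self.starts) and self.starts[i] < end

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Set difference self \\ other."""
        out: list[Interval] = []
        o = list(other)
        for s, e in self:
            cur = s
            for os, oe in o:
                if oe <= cur or os >= e:
                    continue
                if os > cur:
                    out.append((cur, min(os, e)))
                cur = max(cur, oe)
                if cur >= e:
                    break
            if cur < e:
                out.append((cur, e))
        res = IntervalSet.__new__(IntervalSet)
        res.starts = np.array([s for s, _ in out], dtype=np.int64)
        res.ends = np.array([e for _, e in out], dtype=np.int64)
        return res


class GenomeIntervals:
    """Per-chromosome :class:`IntervalSet` collection."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[Interval]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self.by_chrom = {c: IntervalSet(ivs) for c, ivs in by_chrom.items()}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        iv = self.by_chrom.get(chrom)
        return iv.overlaps(start, end) if iv is not None else False

    def contains_point(self, chrom: str, pos: int) -> bool:
        iv = self.by_chrom.get(chrom)
        if iv is None:
            return False
        return bool(iv.contains_points([pos])[0])

    def contains_points(self, chroms, poss) -> np.ndarray:
        """Vectorized point membership over parallel chrom/position arrays."""
        chroms = np.asarray(chroms, dtype=object)
        poss = np.asarray(poss, dtype=np.int64)
        out = np.zeros(len(poss), dtype=bool)
        for c in np.unique(chroms):
            iv = self.by_chrom.get(c)
            if iv is None:
                continue
            mask = chroms == c
            out[mask] = iv.contains_points(poss[mask])
        return out

    @property
    def total_length(self) -> int:
        return sum(iv.total_length for iv in self.by_chrom.values())
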