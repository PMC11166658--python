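"""Interval tracks with stabbing queries (0-based half-open coordinates)."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["Interval", "IntervalTrack"]


class Interval:
    __slots__ = ("contig", "start", "end", "name", "label")

    def __init__(self, contig: str, start: int, end: int,
                 name: Optional[str] = None, label: Optional[str] = None):
        if start < 0 or end <= start:
            raise ValueError(f"bad interval {contig}:{start}-{end}")
        self.contig = contig
        self.start = int(start)
        self.end = int(end)
        self.name = name      # e.g. repeat subfamily
        self.label = label    # e.g. repeat class

    def __len__(self) -> int:
        return self.end - self.start

    def __eq__(self, other) -> bool:
        return (isinstance(other, Interval)
                and (self.contig, self.start, self.end, self.name, self.label)
                == (other.contig, other.start, other.end, other.name, other.label))

    def __repr__(self) -> str:
        extra = f" {self.name}" if self.name else ""
        return f"Interval({self.contig}:{self.start}-{self.end}{extra})"


class IntervalTrack:
    """A set of (possibly overlapping) intervals indexed for point queries.

    Stabbing queries use start-sorted arrays with a running maximum of ends,
    which is exact for overlapping intervals as well.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = sorted(
            intervals, key=lambda iv: (iv.contig, iv.start, iv.end)
        )
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]] = {}
        by_contig: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_contig.setdefault(iv.contig, []).append(i)
        for contig, idxs in by_contig.items():
            starts = np.array([self.intervals[i].start for i in idxs], dtype=np.int64)
            ends = np.array([self.intervals[i].end for i in idxs], dtype=np.int64)
            cummax = np.maximum.accumulate(ends)
            self._index[contig] = (starts, ends, cummax, idxs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_span(self) -> int:
        """Sum of interval lengths (overlaps counted once per interval)."""
        return sum(len(iv) for iv in self.intervals)

    def contigs(self) -> list[str]:
        return list(self._index)

    def validate_bounds(self, genome) -> None:
        for iv in self.intervals:
            if iv.contig not in genome:
                raise ValueError(f"interval on unknown contig {iv.contig!r}")
            if iv.end > genome.length(iv.contig):
                raise ValueError(
                    f"interval {iv!r} exceeds contig length {genome.length(iv.contig)}"
                )

    def overlapping_point(self, contig: str, pos: int) -> list[Interval]:
        """All intervals containing 1-based position ``pos``."""
        entry = self._index.get(contig)
        if entry is None:
            return []
        starts, ends, cummax, idxs = entry
        p0 = pos - 1  # 0-based point
        hi = int(np.searchsorted(starts, p0, side="right"))
        out = []
        j = hi - 1
        while j >= 0 and cummax[j] > p0:
            if ends[j] > p0:
                out.append(self.intervals[idxs[j]])
            j -= 1
        out.reverse()
        return out

    def contains_point(self, contig: str, pos: int) -> bool:
        entry = self._index.get(contig)
        if entry is None:
            return False
        starts, _, cummax, _ = entry
        p0 = pos - 1
        hi = int(np.searchsorted(starts, p0, side="right"))
        return hi > 0 and cummax[hi - 1] > p0

    def point_mask(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 1-based ``positions``.

        Exact only when the track's intervals on ``contig`` are sorted with
        non-decreasing ends after start-sorting; falls back to per-point
        queries otherwise.
        """
        entry = self._index.get(contig)
        if entry is None:
            return np.zeros(len(positions), dtype=bool)
        starts, ends, cummax, _ = entry
        p0 = np.asarray(positions, dtype=np.int64) - 1
        if np.array_equal(ends, cummax):
            hi = np.searchsorted(starts, p0, side="right")
            mask = hi > 0
            mask[mask] = ends[hi[mask] - 1] > p0[mask]
            return mask
        return np.array([self.contains_point(contig, int(p) + 1) for p in p0])

    def coverage_mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean per-base coverage array for one contig."""
        mask = np.zeros(length, dtype=bool)
        entry = self._index.get(contig)
        if entry is None:
            return mask
        starts, ends, _, _ = entry
        for s, e in zip(starts, ends):
            mask[s:min(e, length)] = True
        return mask

    def merged_span(self) -> int:
        """Total genomic bases covered, overlaps merged."""
        total = 0
        for contig, (starts, ends, _, _) in self._index.items():
            cur_s, cur_e = None, None
            for s, e in zip(starts, ends):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        return total
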