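"""Annotation tracks: repeats, CpG islands, TSS, DMRs, simple repeats, CDS."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import GenomeSequence, revcomp
from .intervals import Interval, IntervalTrack

__all__ = ["TSSRecord", "Transcript", "AnnotationSet"]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "other")


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site: 1-based position with strand."""

    contig: str
    pos: int
    strand: str = "+"
    name: Optional[str] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.pos < 1:
            raise ValueError("TSS position must be 1-based >= 1")


@dataclass
class Transcript:
    """A coding model: ordered CDS intervals (0-based half-open) with phases.

    ``frames[i]`` follows GFF phase semantics: the number of bases to skip at
    the 5' end of exon *i* (in transcript orientation) to reach a codon
    boundary. For well-formed models this is ``(3 - cum_len % 3) % 3``.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    frames: Optional[list[int]] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping CDS intervals in transcript {self.transcript_id}"
                )
        if self.coding_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id} not divisible by 3"
            )
        if self.frames is not None:
            expect = self.expected_frames()
            got = list(self.frames)
            if got != expect:
                raise ValueError(
                    f"inconsistent frames for {self.transcript_id}: "
                    f"{got} != expected {expect}"
                )

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Transcript genomic span (0-based half-open)."""
        return self.exons[0][0], self.exons[-1][1]

    def ordered_exons(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') orientation."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def expected_frames(self) -> list[int]:
        out, cum = [], 0
        for s, e in self.ordered_exons():
            out.append((3 - cum % 3) % 3)
            cum += e - s
        if self.strand == "-":
            out.reverse()  # stored in genomic order
        return out

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        seq = genome.contigs[self.contig]
        parts = [seq[s:e] for s, e in self.exons]
        spliced = "".join(parts)
        return spliced if self.strand == "+" else revcomp(spliced)

    def genomic_to_coding(self, pos: int) -> Optional[int]:
        """Map a 1-based genomic position to a 0-based spliced coding index.

        Returns ``None`` if the position is not inside any CDS interval.
        """
        p0 = pos - 1
        cum = 0
        plus_index = None
        for s, e in self.exons:
            if s <= p0 < e:
                plus_index = cum + (p0 - s)
                break
            cum += e - s
        if plus_index is None:
            return None
        if self.strand == "+":
            return plus_index
        return self.coding_length - 1 - plus_index


@dataclass
class AnnotationSet:
    """Interval tracks over a genome.

    Repeat intervals carry ``name`` = subfamily and ``label`` = class
    (LINE/SINE/LTR/other). All tracks except CDS are strandless.
    """

    repeats: IntervalTrack = field(default_factory=IntervalTrack)
    cgi: IntervalTrack = field(default_factory=IntervalTrack)
    tss: list[TSSRecord] = field(default_factory=list)
    dmr: IntervalTrack = field(default_factory=IntervalTrack)
    simple_repeats: IntervalTrack = field(default_factory=IntervalTrack)
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        self._tss_index: dict[str, np.ndarray] = {}
        positions: dict[str, list[int]] = {}
        for t in self.tss:
            positions.setdefault(t.contig, []).append(t.pos)
        for contig, pos in positions.items():
            self._tss_index[contig] = np.array(sorted(pos), dtype=np.int64)
        self._cds_track = IntervalTrack(
            Interval(t.contig, s, e, name=t.transcript_id)
            for t in self.transcripts for s, e in t.exons
        )
        self._span_track = IntervalTrack(
            Interval(t.contig, t.span[0], t.span[1], name=t.transcript_id)
            for t in self.transcripts
        )
        self._tx_by_id = {t.transcript_id: t for t in self.transcripts}

    def validate(self, genome: GenomeSequence) -> None:
        for name in ("repeats", "cgi", "dmr", "simple_repeats"):
            getattr(self, name).validate_bounds(genome)
        for t in self.tss:
            if t.contig not in genome or t.pos > genome.length(t.contig):
                raise ValueError(f"TSS {t} outside genome")
        for tx in self.transcripts:
            if tx.contig not in genome or tx.span[1] > genome.length(tx.contig):
                raise ValueError(f"transcript {tx.transcript_id} outside genome")

    # -- CDS helpers ------------------------------------------------------
    def transcripts_at(self, contig: str, pos: int) -> list[Transcript]:
        """Transcripts whose CDS contains 1-based ``pos``."""
        seen, out = set(), []
        for iv in self._cds_track.overlapping_point(contig, pos):
            if iv.name not in seen:
                seen.add(iv.name)
                out.append(self._tx_by_id[iv.name])
        return out

    def in_transcript_span(self, contig: str, pos: int) -> bool:
        return self._span_track.contains_point(contig, pos)

    def in_cds(self, contig: str, pos: int) -> bool:
        return self._cds_track.contains_point(contig, pos)

    # -- TSS helpers ------------------------------------------------------
    def nearest_tss_distance(self, contig: str, pos: int) -> Optional[int]:
        """Strandless distance to the nearest TSS on the same contig."""
        arr = self._tss_index.get(contig)
        if arr is None or len(arr) == 0:
            return None
        i = int(np.searchsorted(arr, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = abs(int(arr[j]) - pos)
                best = d if best is None else min(best, d)
        return best
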