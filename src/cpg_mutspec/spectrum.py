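"""Strand-collapsed 24-category mutation spectrum and CpG partition stats.

Every substitution is represented on the pyrimidine strand together with its
3'-neighbor base, giving 6 classes x 4 neighbors = 24 categories. Rates are
normalized by the genome-wide abundance of the corresponding (pyrimidine
base, 3'-neighbor) dinucleotide counted on both strands, and reported per
1e9 bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (COMPLEMENT, MUT_CLASSES, PURINES, PYRIMIDINES,
                   GenomeSequence, GenomicPosition, SNVCall,
                   collapse_substitution)

__all__ = [
    "classify",
    "make_call",
    "count_dinucleotide_abundance",
    "SpectrumTable",
    "build_spectrum",
    "CpGPartition",
    "cpg_partition",
    "PartitionCorrelation",
    "correlate_partition",
]

BASES = "ACGT"
NEIGHBORS = tuple(BASES)
#: all 24 (class, 3'-neighbor) spectrum cells
SPECTRUM_CELLS = tuple((mc, nb) for mc in MUT_CLASSES for nb in NEIGHBORS)
#: the 8 collapsed dinucleotide abundance cells
ABUNDANCE_CELLS = tuple((py, nb) for py in "CT" for nb in NEIGHBORS)

PER_BASES = 1e9


def classify(genome: GenomeSequence, position: GenomicPosition,
             ref_base: str, alt_base: str
             ) -> tuple[str, Optional[str], Optional[bool]]:
    """Classify one substitution against its genomic context.

    Returns ``(mut_class, three_prime_base, is_cpg)``. For a purine
    reference, both the substitution and the neighbor are read from the
    reverse-complement strand, so the relevant neighbor sits 5' of the
    variant on the plus strand. Contexts containing N (or falling off the
    contig) yield ``(mut_class, None, None)`` — excluded from the 24 cells.
    """
    contig, pos = position.contig, position.pos
    actual = genome.base(contig, pos)
    if actual != ref_base:
        raise ValueError(
            f"ref mismatch at {contig}:{pos}: call says {ref_base}, "
            f"genome has {actual}"
        )
    mut_class = collapse_substitution(ref_base, alt_base)
    length = genome.length(contig)
    if ref_base in PYRIMIDINES:
        neighbor = genome.base(contig, pos + 1) if pos + 1 <= length else None
    else:
        raw = genome.base(contig, pos - 1) if pos - 1 >= 1 else None
        neighbor = COMPLEMENT[raw] if raw is not None else None
    if neighbor is None or neighbor == "N":
        return mut_class, None, None
    is_cpg = mut_class.startswith("C") and neighbor == "G"
    return mut_class, neighbor, is_cpg


def make_call(genome: GenomeSequence, position: GenomicPosition,
              ref_base: str, alt_base: str,
              vaf: Optional[float] = None) -> SNVCall:
    mut_class, neighbor, is_cpg = classify(genome, position, ref_base, alt_base)
    return SNVCall(position=position, ref_base=ref_base, alt_base=alt_base,
                   vaf=vaf, mut_class=mut_class, three_prime_base=neighbor,
                   is_cpg=is_cpg)


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as int8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_dinucleotide_abundance(genome: GenomeSequence) -> dict[tuple[str, str], int]:
    """Count strand-collapsed dinucleotide sites on both strands.

    Every plus-strand dinucleotide XY contributes one count to (X, Y) if X
    is a pyrimidine, and one count to (comp(Y), comp(X)) if Y is a purine
    (i.e. the minus-strand read of the same two bases starts with a
    pyrimidine). Windows containing N are excluded; overlapping occurrences
    all count.
    """
    counts = np.zeros((4, 4), dtype=np.int64)  # rows: pyrimidine code, cols: neighbor
    for seq in genome.contigs.values():
        codes = encode(seq)
        x, y = codes[:-1], codes[1:]
        valid = (x < 4) & (y < 4)
        x, y = x[valid].astype(np.int64), y[valid].astype(np.int64)
        # plus strand: first base pyrimidine (C=1 or T=3)
        pyr = (x == 1) | (x == 3)
        np.add.at(counts, (x[pyr], y[pyr]), 1)
        # minus strand: second base purine -> revcomp dinucleotide
        pur = (y == 0) | (y == 2)
        np.add.at(counts, (_COMP_CODE[y[pur]].astype(np.int64),
                           _COMP_CODE[x[pur]].astype(np.int64)), 1)
    return {(py, nb): int(counts[_CODE[ord(py)], _CODE[ord(nb)]])
            for py, nb in ABUNDANCE_CELLS}


@dataclass
class SpectrumTable:
    """24-category counts, dinucleotide abundances and per-1e9 rates."""

    counts: dict[tuple[str, str], int]
    abundance: dict[tuple[str, str], int]
    normalized_rate: dict[tuple[str, str], float]
    n_excluded: int = 0
    undefined_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mc, nb in SPECTRUM_CELLS:
            rows.append({
                "mut_class": mc,
                "three_prime_base": nb,
                "count": self.counts[(mc, nb)],
                "abundance": self.abundance[(mc[0], nb)],
                "rate_per_1e9": self.normalized_rate[(mc, nb)],
            })
        return pd.DataFrame(rows)


def build_spectrum(genome: GenomeSequence, calls: Sequence[SNVCall]) -> SpectrumTable:
    """Build the normalized 24-category spectrum for a set of calls.

    Calls already carrying classification fields are trusted; unclassified
    calls are classified against ``genome``. Cells with zero abundance and a
    nonzero count indicate a genome/call mismatch and raise.
    """
    counts = {cell: 0 for cell in SPECTRUM_CELLS}
    n_excluded = 0
    for call in calls:
        if call.three_prime_base is None and call.is_cpg is None:
            mc, nb, _ = classify(genome, call.position, call.ref_base, call.alt_base)
        else:
            mc, nb = call.mut_class, call.three_prime_base
        if nb is None:
            n_excluded += 1
        else:
            counts[(mc, nb)] += 1
    abundance = count_dinucleotide_abundance(genome)
    rates: dict[tuple[str, str], float] = {}
    undefined = []
    for mc, nb in SPECTRUM_CELLS:
        ab = abundance[(mc[0], nb)]
        n = counts[(mc, nb)]
        if ab == 0:
            if n > 0:
                raise ValueError(
                    f"cell ({mc},{nb}) has {n} calls but zero genomic abundance"
                )
            rates[(mc, nb)] = float("nan")
            undefined.append((mc, nb))
        else:
            rates[(mc, nb)] = n / ab * PER_BASES
    return SpectrumTable(counts=counts, abundance=abundance,
                         normalized_rate=rates, n_excluded=n_excluded,
                         undefined_cells=undefined)


@dataclass
class CpGPartition:
    """C>T counts split by CpG context, as counts and % of all SNVs."""

    n_total: int
    n_ct_cpg: int
    n_ct_noncpg: int
    pct_ct_cpg: float
    pct_ct_noncpg: float


def cpg_partition(calls: Sequence[SNVCall]) -> CpGPartition:
    n_total = len(calls)
    n_cpg = sum(1 for c in calls if c.mut_class == "C>T" and c.is_cpg)
    n_non = sum(1 for c in calls
                if c.mut_class == "C>T" and c.is_cpg is False)
    pct_cpg = 100.0 * n_cpg / n_total if n_total else 0.0
    pct_non = 100.0 * n_non / n_total if n_total else 0.0
    return CpGPartition(n_total=n_total, n_ct_cpg=n_cpg, n_ct_noncpg=n_non,
                        pct_ct_cpg=pct_cpg, pct_ct_noncpg=pct_non)


@dataclass
class PartitionCorrelation:
    r_cpg: float
    r_noncpg: float
    flagged: bool = False


def correlate_partition(partitions: Sequence[CpGPartition]) -> PartitionCorrelation:
    """Pearson r of CpG / non-CpG C>T percentages against total SNV counts."""
    if len(partitions) < 3:
        raise ValueError("need at least 3 clones to correlate")
    totals = np.array([p.n_total for p in partitions], dtype=float)
    pct_cpg = np.array([p.pct_ct_cpg for p in partitions], dtype=float)
    pct_non = np.array([p.pct_ct_noncpg for p in partitions], dtype=float)

    def _r(y: np.ndarray) -> tuple[float, bool]:
        if np.ptp(y) == 0 or np.ptp(totals) == 0:
            return float("nan"), True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.pearsonr(totals, y).statistic), False

    r_cpg, f1 = _r(pct_cpg)
    r_non, f2 = _r(pct_non)
    return PartitionCorrelation(r_cpg=r_cpg, r_noncpg=r_non, flagged=f1 or f2)
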