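"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* variant positions are 1-based (VCF convention);
* intervals are 0-based half-open (BED convention);
* sequences are uppercase over the alphabet ``A C G T N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "COMPLEMENT",
    "MUT_CLASSES",
    "PYRIMIDINES",
    "PURINES",
    "GenomeSequence",
    "GenomicPosition",
    "VariantCandidate",
    "SNVCall",
    "collapse_substitution",
    "revcomp",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: the six strand-collapsed substitution classes, pyrimidine reference first
MUT_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_VALID_BASES = frozenset("ACGT")
_VALID_SEQ = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def collapse_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a substitution.

    Purine references are reverse-complemented so that every class has a
    pyrimidine (C or T) reference base.
    """
    if ref not in _VALID_BASES or alt not in _VALID_BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


class GenomeSequence:
    """Named contigs of uppercase ``ACGTN`` bases (insertion-ordered)."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("empty contig name")
            if name in clean:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} has zero length")
            if not _VALID_SEQ.issuperset(seq):
                bad = sorted(set(seq) - _VALID_SEQ)
                raise ValueError(f"contig {name!r} has invalid characters {bad}")
            clean[name] = seq
        self.contigs = clean

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self):
        return iter(self.contigs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.contigs == other.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def base(self, contig: str, pos: int) -> str:
        """Base at a 1-based position."""
        seq = self.contigs[contig]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {contig}:{pos} outside contig (len {len(seq)})")
        return seq[pos - 1]

    def reverse_complement(self) -> "GenomeSequence":
        """Genome with every contig reverse-complemented (same names)."""
        return GenomeSequence({name: revcomp(seq) for name, seq in self.contigs.items()})

    def __repr__(self) -> str:
        return f"GenomeSequence({len(self.contigs)} contigs, {self.total_length} bp)"


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """1-based point coordinate on a named contig."""

    contig: str
    pos: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class VariantCandidate:
    """One candidate SNV with the read-level metrics the filters consume.

    Metric fields default to ``None`` (= not provided); a filter that needs a
    missing metric raises rather than silently passing the record.
    """

    position: GenomicPosition
    ref_base: str
    alt_base: str
    depth: Optional[int] = None
    alt_count: Optional[int] = None
    central_qual: Optional[float] = None
    surround_qual: Optional[float] = None
    gap_mismatch: Optional[int] = None
    parental_alt_count: Optional[int] = None
    sister_alt_counts: Optional[tuple[int, ...]] = None
    known_variant: Optional[bool] = None
    in_simple_repeat: Optional[bool] = None
    in_homopolymer: Optional[bool] = None

    def __post_init__(self):
        if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
            raise ValueError(
                f"ref/alt must be A/C/G/T, got {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref equals alt ({self.ref_base}) at {self.position}")
        if self.depth is not None and self.alt_count is not None:
            if not 0 <= self.alt_count <= self.depth:
                raise ValueError(
                    f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
                )
        if self.sister_alt_counts is not None:
            self.sister_alt_counts = tuple(self.sister_alt_counts)

    @property
    def vaf(self) -> Optional[float]:
        if self.depth in (None, 0) or self.alt_count is None:
            return None
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.position.contig, self.position.pos, self.ref_base, self.alt_base)


@dataclass
class SNVCall:
    """A filtered, accepted SNV with its strand-collapsed classification.

    ``three_prime_base`` is the 3'-neighbor on the pyrimidine strand;
    ``None`` means the context could not be classified (N base or contig
    edge).
    """

    position: GenomicPosition
    ref_base: str
    alt_base: str
    vaf: Optional[float] = None
    mut_class: Optional[str] = None
    three_prime_base: Optional[str] = None
    is_cpg: Optional[bool] = None

    def __post_init__(self):
        if self.mut_class is None:
            self.mut_class = collapse_substitution(self.ref_base, self.alt_base)
        elif self.mut_class != collapse_substitution(self.ref_base, self.alt_base):
            raise ValueError(
                f"mut_class {self.mut_class} inconsistent with "
                f"{self.ref_base}>{self.alt_base}"
            )
        if self.is_cpg:
            if not self.mut_class.startswith("C"):
                raise ValueError("is_cpg requires a C-reference class")
            if self.three_prime_base != "G":
                raise ValueError("is_cpg requires three_prime_base == G")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.position.contig, self.position.pos, self.ref_base, self.alt_base)

    @property
    def is_cpg_ct(self) -> bool:
        return bool(self.is_cpg) and self.mut_class == "C>T"

    @property
    def is_noncpg_ct(self) -> bool:
        return self.mut_class == "C>T" and self.is_cpg is False
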