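"""Codon-level consequence annotation and the CpG C>T codon census."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotations import AnnotationSet, Transcript
from .core import COMPLEMENT, GenomeSequence, SNVCall

__all__ = [
    "GENETIC_CODE",
    "CodingEffect",
    "annotate_coding",
    "cpg_ct_codon_census",
    "EffectSummary",
    "summarize_effects",
]

# standard genetic code, one-letter amino acids, '*' = stop
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SEVERITY = {"nonsense": 0, "missense": 1, "silent": 2}


def _effect(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == ref_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


@dataclass
class CodingEffect:
    transcript_id: str
    contig: str
    pos: int                # 1-based genomic position of the variant
    codon_index: int        # 0-based codon number within the CDS
    codon_position: int     # 1..3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str             # nonsense | missense | silent
    is_cpg_ct: bool

    def __post_init__(self):
        diffs = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
        if diffs != 1:
            raise ValueError(
                f"codons {self.ref_codon}->{self.alt_codon} differ at {diffs} positions"
            )
        if GENETIC_CODE[self.ref_codon] != self.ref_aa \
                or GENETIC_CODE[self.alt_codon] != self.alt_aa:
            raise ValueError("amino acids inconsistent with the genetic code")
        if self.effect != _effect(self.ref_aa, self.alt_aa):
            raise ValueError("effect label inconsistent with amino acids")


def annotate_coding(calls: Sequence[SNVCall], annotations: AnnotationSet,
                    genome: GenomeSequence) -> list[CodingEffect]:
    """Annotate calls falling in CDS with their codon-level consequence.

    Minus-strand transcripts are handled by mapping into spliced coding
    coordinates and complementing the alleles. Overlapping transcripts give
    one effect each.
    """
    effects: list[CodingEffect] = []
    spliced_cache: dict[str, str] = {}
    for call in calls:
        contig, pos = call.position.contig, call.position.pos
        for tx in annotations.transcripts_at(contig, pos):
            coding_idx = tx.genomic_to_coding(pos)
            if coding_idx is None:
                continue
            spliced = spliced_cache.get(tx.transcript_id)
            if spliced is None:
                spliced = tx.spliced_sequence(genome)
                spliced_cache[tx.transcript_id] = spliced
            ref_c = call.ref_base if tx.strand == "+" else COMPLEMENT[call.ref_base]
            alt_c = call.alt_base if tx.strand == "+" else COMPLEMENT[call.alt_base]
            if spliced[coding_idx] != ref_c:
                raise ValueError(
                    f"CDS sequence of {tx.transcript_id} disagrees with call "
                    f"ref at {contig}:{pos}"
                )
            k, within = divmod(coding_idx, 3)
            ref_codon = spliced[3 * k:3 * k + 3]
            alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
            ref_aa = GENETIC_CODE[ref_codon]
            alt_aa = GENETIC_CODE[alt_codon]
            effects.append(CodingEffect(
                transcript_id=tx.transcript_id, contig=contig, pos=pos,
                codon_index=k, codon_position=within + 1,
                ref_codon=ref_codon, alt_codon=alt_codon,
                ref_aa=ref_aa, alt_aa=alt_aa,
                effect=_effect(ref_aa, alt_aa),
                is_cpg_ct=bool(call.is_cpg_ct),
            ))
    return effects


def cpg_ct_codon_census() -> pd.DataFrame:
    """All codon changes reachable by a CpG-context C>T substitution.

    Enumerates 64 codons x 3 positions on both strands of the coding frame:
    a plus-strand C>T whose 3'-neighbor is G, or a minus-strand event seen
    as G>A on the coding strand with a 5'-neighbor C. CpG contexts spanning
    a codon boundary are included and their required flanking base recorded
    (``required_flank``: ``3'G`` means the next codon must start with G,
    ``5'C`` that the previous codon must end with C).
    """
    rows = []
    codons = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
    for codon in codons:
        for k in range(3):
            # plus strand: C>T needs 3'-neighbor G
            if codon[k] == "C":
                if k < 2:
                    in_context = codon[k + 1] == "G"
                    flank = None
                else:
                    in_context = True
                    flank = "3'G"
                if in_context:
                    alt = codon[:k] + "T" + codon[k + 1:]
                    rows.append(_census_row(codon, alt, k, "plus", flank))
            # minus strand: G>A on the coding strand needs 5'-neighbor C
            if codon[k] == "G":
                if k > 0:
                    in_context = codon[k - 1] == "C"
                    flank = None
                else:
                    in_context = True
                    flank = "5'C"
                if in_context:
                    alt = codon[:k] + "A" + codon[k + 1:]
                    rows.append(_census_row(codon, alt, k, "minus", flank))
    return pd.DataFrame(rows)


def _census_row(ref_codon: str, alt_codon: str, k: int, strand: str,
                flank: Optional[str]) -> dict:
    ref_aa = GENETIC_CODE[ref_codon]
    alt_aa = GENETIC_CODE[alt_codon]
    return {
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "codon_position": k + 1,
        "strand": strand,
        "required_flank": flank or "",
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "effect": _effect(ref_aa, alt_aa),
    }


@dataclass
class EffectSummary:
    n_total: int
    n_nonsense: int
    n_missense: int
    n_silent: int
    arg_count: int
    arg_fraction_pct: float
    substitutions: pd.DataFrame  # ref_aa, alt_aa, count

    @property
    def ratio(self) -> tuple[int, int, int]:
        return (self.n_nonsense, self.n_missense, self.n_silent)


def summarize_effects(effects: Sequence[CodingEffect]) -> EffectSummary:
    """Effect-class counts, amino-acid substitution table and Arg fraction.

    A variant hitting several transcripts is counted once, by its most
    severe effect (nonsense > missense > silent).
    """
    best: dict[tuple[str, int], CodingEffect] = {}
    for e in effects:
        key = (e.contig, e.pos)
        cur = best.get(key)
        if cur is None or SEVERITY[e.effect] < SEVERITY[cur.effect]:
            best[key] = e
    chosen = list(best.values())
    n = len(chosen)
    counts = {"nonsense": 0, "missense": 0, "silent": 0}
    subs: dict[tuple[str, str], int] = {}
    arg = 0
    for e in chosen:
        counts[e.effect] += 1
        subs[(e.ref_aa, e.alt_aa)] = subs.get((e.ref_aa, e.alt_aa), 0) + 1
        if e.ref_aa == "R":
            arg += 1
    sub_df = pd.DataFrame(
        [{"ref_aa": r, "alt_aa": a, "count": c} for (r, a), c in sorted(subs.items())]
    )
    return EffectSummary(
        n_total=n,
        n_nonsense=counts["nonsense"],
        n_missense=counts["missense"],
        n_silent=counts["silent"],
        arg_count=arg,
        arg_fraction_pct=100.0 * arg / n if n else 0.0,
        substitutions=sub_df,
    )
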