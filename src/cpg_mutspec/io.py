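"""Readers and writers for FASTA, VCF, BED and GFF-like CDS tables.

The VCF dialect used for candidates stores read-level metrics in INFO:

========  =======  ===========================================
tag       type     meaning
========  =======  ===========================================
``DP``    Integer  read depth (required)
``VAC``   Integer  variant-allele read count (required)
``CQ``    Float    central base quality (required)
``SQ``    Float    mean surrounding-window quality (required)
``GM``    Integer  gap + mismatch count in the window (required)
``PAC``   Integer  variant-allele reads in the parental sample
``SAC``   Integer  variant-allele reads per sister clone (list)
``KNOWN`` Flag     listed in a known-variant database
``SRP``   Flag     inside a simple-repeat region
``HPR``   Flag     inside a homopolymer run
========  =======  ===========================================

Tags absent from the header map to ``None`` on the candidate (never to a
value that silently passes a filter). The five required tags must be
declared and present on every record.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam

from .annotations import AnnotationSet, Transcript, TSSRecord
from .core import GenomeSequence, GenomicPosition, SNVCall, VariantCandidate
from .intervals import Interval, IntervalTrack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

REQUIRED_INFO_TAGS = ("DP", "VAC", "CQ", "SQ", "GM")

_INFO_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=VAC,Number=1,Type=Integer,Description="Variant allele read count">',
    '##INFO=<ID=CQ,Number=1,Type=Float,Description="Central base quality">',
    '##INFO=<ID=SQ,Number=1,Type=Float,Description="Mean surrounding window quality">',
    '##INFO=<ID=GM,Number=1,Type=Integer,Description="Gap and mismatch count in window">',
    '##INFO=<ID=PAC,Number=1,Type=Integer,Description="Variant allele reads in parental sample">',
    '##INFO=<ID=SAC,Number=.,Type=Integer,Description="Variant allele reads per sister clone">',
    '##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Known variant (dbSNP-listed)">',
    '##INFO=<ID=SRP,Number=0,Type=Flag,Description="Inside simple repeat">',
    '##INFO=<ID=HPR,Number=0,Type=Flag,Description="Inside homopolymer run">',
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: PathLike) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase is normalized to uppercase and any non-ACGTN character
    becomes ``N``. Duplicate contig names or an empty file are errors.
    """
    contigs: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []

    def _flush():
        if name is None:
            return
        if name in contigs:
            raise ValueError(f"duplicate contig name in FASTA: {name!r}")
        contigs[name] = _normalize_seq("".join(chunks))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA data before first header")
                chunks.append(line)
    _flush()
    if not contigs:
        raise ValueError(f"empty FASTA file: {path}")
    return GenomeSequence(contigs)


_ALLOWED = set("ACGTN")


def _normalize_seq(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _ALLOWED:
        return seq
    return "".join(c if c in _ALLOWED else "N" for c in seq)


def write_genome(genome: GenomeSequence, path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_candidates_vcf(candidates: Sequence[VariantCandidate], path: PathLike,
                         genome: Optional[GenomeSequence] = None) -> None:
    """Write candidates as an uncompressed VCF 4.2 file with metric tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cpg-mutspec\n")
        if genome is not None:
            for name, seq in genome.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        else:
            for name in dict.fromkeys(c.position.contig for c in candidates):
                fh.write(f"##contig=<ID={name}>\n")
        for line in _INFO_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            info = []
            if c.depth is not None:
                info.append(f"DP={c.depth}")
            if c.alt_count is not None:
                info.append(f"VAC={c.alt_count}")
            if c.central_qual is not None:
                info.append(f"CQ={c.central_qual:g}")
            if c.surround_qual is not None:
                info.append(f"SQ={c.surround_qual:g}")
            if c.gap_mismatch is not None:
                info.append(f"GM={c.gap_mismatch}")
            if c.parental_alt_count is not None:
                info.append(f"PAC={c.parental_alt_count}")
            if c.sister_alt_counts:  # empty tuple = no sisters, tag omitted
                info.append("SAC=" + ",".join(map(str, c.sister_alt_counts)))
            if c.known_variant:
                info.append("KNOWN")
            if c.in_simple_repeat:
                info.append("SRP")
            if c.in_homopolymer:
                info.append("HPR")
            fh.write(
                f"{c.position.contig}\t{c.position.pos}\t.\t{c.ref_base}\t"
                f"{c.alt_base}\t.\t.\t{';'.join(info) or '.'}\n"
            )


def write_calls_vcf(calls: Sequence[SNVCall], path: PathLike,
                    genome: Optional[GenomeSequence] = None) -> None:
    """Write accepted calls as VCF with VAF/class annotations."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cpg-mutspec\n")
        if genome is not None:
            for name, seq in genome.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=MC,Number=1,Type=String,Description="Strand-collapsed mutation class">\n')
        fh.write('##INFO=<ID=TPB,Number=1,Type=String,Description="3-prime neighbor on pyrimidine strand">\n')
        fh.write('##INFO=<ID=CPG,Number=0,Type=Flag,Description="CpG context">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = []
            if c.vaf is not None:
                info.append(f"VAF={c.vaf:.6g}")
            info.append(f"MC={c.mut_class}")
            if c.three_prime_base is not None:
                info.append(f"TPB={c.three_prime_base}")
            if c.is_cpg:
                info.append("CPG")
            fh.write(
                f"{c.position.contig}\t{c.position.pos}\t.\t{c.ref_base}\t"
                f"{c.alt_base}\t.\t.\t{';'.join(info)}\n"
            )


def read_variants(path: PathLike,
                  genome: Optional[GenomeSequence] = None) -> list[VariantCandidate]:
    """Read SNV candidates from a VCF file.

    Multi-allelic records are split into one candidate per alt allele;
    non-SNV alleles are skipped with a logged count. When ``genome`` is
    supplied the REF base is checked against it.
    """
    vcf = pysam.VariantFile(str(path))
    declared = set(vcf.header.info.keys())
    missing = [t for t in REQUIRED_INFO_TAGS if t not in declared]
    if missing:
        raise ValueError(f"VCF {path} missing required INFO tag(s): {missing}")
    has = {t: t in declared for t in ("PAC", "SAC", "KNOWN", "SRP", "HPR")}

    out: list[VariantCandidate] = []
    skipped = 0
    for rec in vcf:
        ref = rec.ref.upper() if rec.ref else ""
        if genome is not None and len(ref) == 1:
            actual = genome.base(rec.contig, rec.pos)
            if actual != ref:
                raise ValueError(
                    f"REF mismatch at {rec.contig}:{rec.pos}: VCF says {ref}, "
                    f"genome has {actual}"
                )
        for alt in (rec.alts or ()):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                skipped += 1
                continue
            info = rec.info
            vals = {}
            for tag in REQUIRED_INFO_TAGS:
                if tag not in info:
                    raise ValueError(
                        f"record {rec.contig}:{rec.pos} missing required tag {tag}"
                    )
                vals[tag] = info[tag]
            sac = None
            if has["SAC"]:
                # declared but absent on a record = empty sister list
                if "SAC" in info:
                    raw = info["SAC"]
                    sac = tuple(int(v)
                                for v in (raw if isinstance(raw, tuple) else (raw,)))
                else:
                    sac = ()
            out.append(VariantCandidate(
                position=GenomicPosition(rec.contig, rec.pos),
                ref_base=ref,
                alt_base=alt,
                depth=int(vals["DP"]),
                alt_count=int(vals["VAC"]),
                central_qual=float(vals["CQ"]),
                surround_qual=float(vals["SQ"]),
                gap_mismatch=int(vals["GM"]),
                parental_alt_count=(int(info["PAC"]) if has["PAC"] and "PAC" in info
                                    else None),
                sister_alt_counts=sac,
                known_variant=(bool(info.get("KNOWN", False)) if has["KNOWN"] else None),
                in_simple_repeat=(bool(info.get("SRP", False)) if has["SRP"] else None),
                in_homopolymer=(bool(info.get("HPR", False)) if has["HPR"] else None),
            ))
    if skipped:
        logger.info("read_variants(%s): skipped %d non-SNV allele(s)", path, skipped)
    read_variants.last_skipped = skipped  # inspectable counter for reports
    return out


read_variants.last_skipped = 0


def read_calls(path: PathLike,
               genome: Optional[GenomeSequence] = None) -> list[SNVCall]:
    """Read classified calls written by :func:`write_calls_vcf`."""
    vcf = pysam.VariantFile(str(path))
    out: list[SNVCall] = []
    for rec in vcf:
        for alt in (rec.alts or ()):
            if len(rec.ref) != 1 or len(alt) != 1:
                continue
            info = rec.info
            tpb = info.get("TPB")
            out.append(SNVCall(
                position=GenomicPosition(rec.contig, rec.pos),
                ref_base=rec.ref.upper(),
                alt_base=alt.upper(),
                vaf=float(info["VAF"]) if "VAF" in info else None,
                three_prime_base=str(tpb) if tpb is not None else None,
                is_cpg=bool(info.get("CPG", False)) if tpb is not None else None,
            ))
    return out


# ---------------------------------------------------------------------------
# BED / GFF tracks
# ---------------------------------------------------------------------------

def read_bed_track(path: PathLike) -> IntervalTrack:
    """Read a BED3+ file; column 4 becomes ``name``, column 5 ``label``.

    For repeat tracks the convention is name=subfamily, label=class
    (e.g. ``c1  0  300  AluY  SINE``). An empty file yields an empty track.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line in {path}: {line!r}")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            label = fields[4] if len(fields) > 4 and fields[4] != "." else None
            intervals.append(Interval(contig, start, end, name=name, label=label))
    return IntervalTrack(intervals)


def write_bed_track(track: IntervalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.label is not None:
                fields.append(iv.name or ".")
            if iv.label is not None:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


def read_tss_bed(path: PathLike) -> list[TSSRecord]:
    """Read TSS positions from BED (position = interval start, 0-based)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed TSS BED line: {line!r}")
            contig, start = fields[0], int(fields[1])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "+"
            out.append(TSSRecord(contig=contig, pos=start + 1, strand=strand, name=name))
    return out


def write_tss_bed(tss: Sequence[TSSRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in tss:
            fh.write(f"{t.contig}\t{t.pos - 1}\t{t.pos}\t{t.name or '.'}\t0\t{t.strand}\n")


def read_cds_gff(path: PathLike) -> list[Transcript]:
    """Read a GFF-like CDS table into transcripts.

    Expected columns: seqid, source, type, start (1-based), end, score,
    strand, phase, attributes with ``transcript_id`` (GTF style) or
    ``Parent=``/``ID=`` (GFF3 style). Only ``CDS`` features are used.
    """
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, phase, attrs = fields[:9]
            if ftype != "CDS":
                continue
            tid = _parse_transcript_id(attrs)
            g = groups.setdefault(tid, {"contig": seqid, "strand": strand,
                                        "exons": [], "frames": {}})
            s0, e0 = int(start) - 1, int(end)
            g["exons"].append((s0, e0))
            g["frames"][(s0, e0)] = None if phase == "." else int(phase)
    out = []
    for tid, g in groups.items():
        exons = sorted(g["exons"])
        frames = [g["frames"][ex] for ex in exons]
        if any(f is None for f in frames):
            frames = None
        out.append(Transcript(transcript_id=tid, contig=g["contig"],
                              strand=g["strand"], exons=exons, frames=frames))
    return out


def _parse_transcript_id(attrs: str) -> str:
    for part in attrs.replace("; ", ";").split(";"):
        part = part.strip()
        if not part:
            continue
        if part.startswith("transcript_id"):
            return part.split(None, 1)[1].strip().strip('"')
        for key in ("Parent=", "ID=", "transcript_id="):
            if part.startswith(key):
                return part[len(key):].strip('"')
    raise ValueError(f"no transcript id in GFF attributes: {attrs!r}")


def write_cds_gff(transcripts: Sequence[Transcript], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            frames = tx.frames or tx.expected_frames()
            for (s, e), frame in zip(tx.exons, frames):
                fh.write(
                    f"{tx.contig}\tcpg-mutspec\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{tx.strand}\t{frame}\tID={tx.transcript_id}\n"
                )


def read_annotations(repeats: Optional[PathLike] = None,
                     cgi: Optional[PathLike] = None,
                     tss: Optional[PathLike] = None,
                     dmr: Optional[PathLike] = None,
                     simple_repeats: Optional[PathLike] = None,
                     cds: Optional[PathLike] = None,
                     genome: Optional[GenomeSequence] = None) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from per-track files (all optional)."""
    ann = AnnotationSet(
        repeats=read_bed_track(repeats) if repeats else IntervalTrack(),
        cgi=read_bed_track(cgi) if cgi else IntervalTrack(),
        tss=read_tss_bed(tss) if tss else [],
        dmr=read_bed_track(dmr) if dmr else IntervalTrack(),
        simple_repeats=read_bed_track(simple_repeats) if simple_repeats else IntervalTrack(),
        transcripts=read_cds_gff(cds) if cds else [],
    )
    if genome is not None:
        ann.validate(genome)
    return ann
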