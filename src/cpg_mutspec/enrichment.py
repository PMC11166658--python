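"""Regional distribution and enrichment statistics for CpG C>T calls.

Covers genomic compartment assignment (CDS > intron > intergenic),
retrotransposon class percentages with a two-proportion Z-test, SINE
subfamily enrichment relative to a germline comparator, the DMR in/out
rate ratio normalized by CpG (or other-C) site abundance, CGI / CGI-shore
counts and the nearest-TSS distance profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet
from .core import GenomeSequence, SNVCall
from .intervals import IntervalTrack
from .spectrum import encode

__all__ = [
    "RegionAssignment",
    "assign_regions",
    "retrotransposon_rates",
    "sine_subfamily_enrichment",
    "DMRRatio",
    "dmr_ratio",
    "cgi_shore_counts",
    "tss_distance_profile",
    "z_test_two_proportions",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR")
DEFAULT_SHORE_WIDTH = 5000

#: default Alu subfamily groupings: family sums, with AluY kept separate
#: from the younger AluYa..AluYk subfamilies
DEFAULT_SUBFAMILY_GROUPS = {
    "AluJ": lambda s: s.startswith("AluJ"),
    "AluS": lambda s: s.startswith("AluS"),
    "AluY": lambda s: s == "AluY",
    "AluYa-k": lambda s: s.startswith("AluY") and len(s) > 4,
}


# ---------------------------------------------------------------------------
# Compartments and overlap flags
# ---------------------------------------------------------------------------

@dataclass
class RegionAssignment:
    """Per-variant compartment and annotation overlap flags."""

    table: pd.DataFrame

    @property
    def compartment_counts(self) -> dict[str, int]:
        counts = self.table["compartment"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("CDS", "intron", "intergenic")}


def assign_regions(calls: Sequence[SNVCall], annotations: AnnotationSet,
                   shore_width: int = DEFAULT_SHORE_WIDTH) -> RegionAssignment:
    """Assign each call one compartment and independent overlap flags.

    Compartment precedence is CDS > intron > intergenic, where intron means
    inside a transcript span but not in CDS. Flags (repeat class/subfamily,
    CGI, CGI shore, DMR) are computed by interval intersection of the
    1-based variant point against 0-based half-open intervals.
    """
    rows = []
    for call in calls:
        contig, pos = call.position.contig, call.position.pos
        if annotations.in_cds(contig, pos):
            compartment = "CDS"
        elif annotations.in_transcript_span(contig, pos):
            compartment = "intron"
        else:
            compartment = "intergenic"
        repeat_hits = annotations.repeats.overlapping_point(contig, pos)
        classes = {iv.label for iv in repeat_hits}
        subfamily = None
        if repeat_hits:
            # longest-overlap wins; a point overlap means the whole interval
            best = max(repeat_hits, key=len)
            subfamily = best.name
        in_cgi = annotations.cgi.contains_point(contig, pos)
        rows.append({
            "contig": contig, "pos": pos,
            "mut_class": call.mut_class, "is_cpg": call.is_cpg,
            "compartment": compartment,
            "in_line": "LINE" in classes,
            "in_sine": "SINE" in classes,
            "in_ltr": "LTR" in classes,
            "repeat_subfamily": subfamily,
            "in_cgi": in_cgi,
            "in_cgi_shore": (not in_cgi
                             and _in_shore(annotations.cgi, contig, pos, shore_width)),
            "in_dmr": annotations.dmr.contains_point(contig, pos),
        })
    columns = ["contig", "pos", "mut_class", "is_cpg", "compartment",
               "in_line", "in_sine", "in_ltr", "repeat_subfamily",
               "in_cgi", "in_cgi_shore", "in_dmr"]
    return RegionAssignment(table=pd.DataFrame(rows, columns=columns))


def _in_shore(cgi: IntervalTrack, contig: str, pos: int, width: int) -> bool:
    p0 = pos - 1
    for iv in cgi:
        if iv.contig != contig:
            continue
        if iv.start - width <= p0 < iv.start or iv.end <= p0 < iv.end + width:
            return True
    return False


# ---------------------------------------------------------------------------
# Retrotransposon class rates
# ---------------------------------------------------------------------------

def retrotransposon_rates(calls: Sequence[SNVCall],
                          annotations: AnnotationSet) -> pd.DataFrame:
    """Per-class (LINE/SINE/LTR) C>T percentages and CpG-vs-non-CpG Z-test.

    For each class, ``pct_cpg_ct`` is the percentage of all CpG C>T calls
    falling inside the class; ``pct_noncpg_ct`` likewise for non-CpG C>T.
    ``pct_all_cpg_ct`` / ``pct_all_noncpg_ct`` use all mutations as the
    denominator (both readings of "percentages of mutation positions" are
    emitted). The Z-test compares the two proportions per class.
    """
    if not annotations.repeats:
        raise ValueError("repeat track is empty")
    cpg_ct = [c for c in calls if c.is_cpg_ct]
    noncpg_ct = [c for c in calls if c.is_noncpg_ct]
    n_all = len(calls)
    rows = []
    for klass in REPEAT_CLASSES:
        track = IntervalTrack(iv for iv in annotations.repeats if iv.label == klass)
        x1 = sum(1 for c in cpg_ct
                 if track.contains_point(c.position.contig, c.position.pos))
        x2 = sum(1 for c in noncpg_ct
                 if track.contains_point(c.position.contig, c.position.pos))
        n1, n2 = len(cpg_ct), len(noncpg_ct)
        z = p = math.nan
        if n1 > 0 and n2 > 0:
            z, p = z_test_two_proportions(x1, n1, x2, n2)
        rows.append({
            "repeat_class": klass,
            "n_cpg_ct": x1,
            "pct_cpg_ct": 100.0 * x1 / n1 if n1 else math.nan,
            "n_noncpg_ct": x2,
            "pct_noncpg_ct": 100.0 * x2 / n2 if n2 else math.nan,
            "pct_all_cpg_ct": 100.0 * x1 / n_all if n_all else math.nan,
            "pct_all_noncpg_ct": 100.0 * x2 / n_all if n_all else math.nan,
            "z": z,
            "p_value": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SINE subfamily enrichment
# ---------------------------------------------------------------------------

def _subfamily_counts(calls: Sequence[SNVCall],
                      sine_track: IntervalTrack) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in calls:
        if not c.is_cpg_ct:
            continue
        hits = [iv for iv in
                sine_track.overlapping_point(c.position.contig, c.position.pos)]
        if not hits:
            continue
        best = max(hits, key=len)  # longest-overlap subfamily wins
        counts[best.name] = counts.get(best.name, 0) + 1
    return counts


def sine_subfamily_enrichment(ipsc_calls: Sequence[SNVCall],
                              germline_calls: Sequence[SNVCall],
                              annotations: AnnotationSet,
                              groups: Optional[Mapping] = None,
                              scale_to: str = "AluJ") -> pd.DataFrame:
    """Per-subfamily CpG C>T percentages, cohort ratio and AluJ-relative ratio.

    Percentages are of all CpG C>T calls inside whole SINEs, per cohort.
    ``ratio`` = pct(first cohort) / pct(germline); ``ratio_rel`` rescales so
    the ``scale_to`` group equals 1. Groups default to AluJ/AluS/AluY/AluYa-k
    label predicates; rows are emitted per subfamily label and per group.
    """
    sine_track = IntervalTrack(iv for iv in annotations.repeats
                               if iv.label == "SINE")
    if not sine_track:
        raise ValueError("no SINE intervals in repeat track")
    groups = dict(groups) if groups is not None else dict(DEFAULT_SUBFAMILY_GROUPS)
    counts_i = _subfamily_counts(ipsc_calls, sine_track)
    counts_g = _subfamily_counts(germline_calls, sine_track)
    total_i = sum(counts_i.values())
    total_g = sum(counts_g.values())
    labels = sorted(set(counts_i) | set(counts_g)
                    | {iv.name for iv in sine_track if iv.name})

    def _row(name: str, members: list[str], kind: str) -> dict:
        n_i = sum(counts_i.get(m, 0) for m in members)
        n_g = sum(counts_g.get(m, 0) for m in members)
        pct_i = 100.0 * n_i / total_i if total_i else math.nan
        pct_g = 100.0 * n_g / total_g if total_g else math.nan
        ratio = pct_i / pct_g if pct_g and not math.isnan(pct_g) else math.nan
        return {"subfamily": name, "kind": kind, "n_ipsc": n_i, "n_germline": n_g,
                "pct_ipsc": pct_i, "pct_germline": pct_g, "ratio": ratio}

    rows = [_row(lab, [lab], "subfamily") for lab in labels]
    for gname, pred in groups.items():
        members = [lab for lab in labels if pred(lab)]
        rows.append(_row(gname, members, "group"))
    df = pd.DataFrame(rows)
    anchor = df.loc[(df["subfamily"] == scale_to) & (df["kind"] == "group"), "ratio"]
    if anchor.empty:
        anchor = df.loc[df["subfamily"] == scale_to, "ratio"]
    anchor_val = float(anchor.iloc[0]) if len(anchor) else math.nan
    if not anchor_val or math.isnan(anchor_val):
        warnings.warn(f"anchor group {scale_to!r} has undefined ratio; "
                      "ratio_rel left unscaled")
        df["ratio_rel"] = df["ratio"]
    else:
        df["ratio_rel"] = df["ratio"] / anchor_val
    return df


# ---------------------------------------------------------------------------
# DMR ratio
# ---------------------------------------------------------------------------

@dataclass
class DMRRatio:
    """In/out C>T rates normalized by site abundance, for CpG and other C."""

    cpg_rate_in: float
    cpg_rate_out: float
    cpg_ratio: float
    noncpg_rate_in: float
    noncpg_rate_out: float
    noncpg_ratio: float
    sites_cpg_in: int = 0
    sites_cpg_out: int = 0
    sites_noncpg_in: int = 0
    sites_noncpg_out: int = 0


def _site_masks(genome: GenomeSequence, contig: str):
    """Per-base masks of CpG-context and other-C-context sites (both strands).

    A position is a CpG site if it is a C followed by G or a G preceded by C
    (the same site set the strand-collapsed classifier maps to (C, G)); an
    other-C site if its collapsed context is C with a non-G neighbor.
    """
    b = encode(genome.contigs[contig]).astype(np.int64)
    n = len(b)
    cpg = np.zeros(n, dtype=bool)
    nonc = np.zeros(n, dtype=bool)
    # plus-strand C with valid next base
    c_pos = np.nonzero((b[:-1] == 1) & (b[1:] < 4))[0]
    nxt = b[c_pos + 1]
    cpg[c_pos[nxt == 2]] = True
    nonc[c_pos[nxt != 2]] = True
    # plus-strand G with valid previous base -> C on minus strand,
    # collapsed neighbor = comp(prev); CpG iff prev == C
    g_pos = np.nonzero((b[1:] == 2) & (b[:-1] < 4))[0] + 1
    prv = b[g_pos - 1]
    cpg[g_pos[prv == 1]] = True
    nonc[g_pos[prv != 1]] = True
    return cpg, nonc


def dmr_ratio(calls: Sequence[SNVCall], annotations: AnnotationSet,
              genome: GenomeSequence) -> DMRRatio:
    """Ratio of C>T rates inside vs outside DMRs.

    The CpG C>T rate is normalized by the number of CpG-context sites, the
    non-CpG C>T rate by the number of other-C sites, counted on both strands
    inside and outside the DMR track. An empty DMR track is undefined.
    """
    if not annotations.dmr:
        raise ValueError("DMR track is empty")
    sites = {"cpg_in": 0, "cpg_out": 0, "nonc_in": 0, "nonc_out": 0}
    for contig in genome.contigs:
        cpg, nonc = _site_masks(genome, contig)
        in_dmr = annotations.dmr.coverage_mask(contig, genome.length(contig))
        sites["cpg_in"] += int((cpg & in_dmr).sum())
        sites["cpg_out"] += int((cpg & ~in_dmr).sum())
        sites["nonc_in"] += int((nonc & in_dmr).sum())
        sites["nonc_out"] += int((nonc & ~in_dmr).sum())

    counts = {"cpg_in": 0, "cpg_out": 0, "nonc_in": 0, "nonc_out": 0}
    for c in calls:
        if c.mut_class != "C>T" or c.is_cpg is None:
            continue
        inside = annotations.dmr.contains_point(c.position.contig, c.position.pos)
        key = ("cpg" if c.is_cpg else "nonc") + ("_in" if inside else "_out")
        counts[key] += 1

    def _rate(kind: str, where: str) -> float:
        s = sites[f"{kind}_{where}"]
        return counts[f"{kind}_{where}"] / s if s else math.nan

    def _ratio(rin: float, rout: float) -> float:
        if math.isnan(rin) or math.isnan(rout):
            return math.nan
        if rout == 0:
            warnings.warn("outside rate is zero; DMR ratio undefined")
            return math.nan
        return rin / rout

    cr_in, cr_out = _rate("cpg", "in"), _rate("cpg", "out")
    nr_in, nr_out = _rate("nonc", "in"), _rate("nonc", "out")
    return DMRRatio(
        cpg_rate_in=cr_in, cpg_rate_out=cr_out, cpg_ratio=_ratio(cr_in, cr_out),
        noncpg_rate_in=nr_in, noncpg_rate_out=nr_out,
        noncpg_ratio=_ratio(nr_in, nr_out),
        sites_cpg_in=sites["cpg_in"], sites_cpg_out=sites["cpg_out"],
        sites_noncpg_in=sites["nonc_in"], sites_noncpg_out=sites["nonc_out"],
    )


# ---------------------------------------------------------------------------
# CGI / shore counts and TSS distance
# ---------------------------------------------------------------------------

def cgi_shore_counts(call_sets: Union[Mapping[str, Sequence[SNVCall]],
                                      Sequence[Sequence[SNVCall]]],
                     annotations: AnnotationSet,
                     shore_width: int = DEFAULT_SHORE_WIDTH,
                     cpg_ct_only: bool = True) -> pd.DataFrame:
    """Per-clone counts of calls inside CGIs and inside CGI shores.

    The shore is the union of ±``shore_width`` flanks minus any CGI overlap
    (flanks are implicitly clipped at contig ends since variant positions
    are always in-bounds). A call inside a CGI is not counted in the shore.
    """
    if not annotations.cgi:
        raise ValueError("CGI track is empty")
    if not isinstance(call_sets, Mapping):
        call_sets = {f"clone{i + 1}": c for i, c in enumerate(call_sets)}
    rows = []
    for name, calls in call_sets.items():
        use = [c for c in calls if (not cpg_ct_only) or c.is_cpg_ct]
        n_cgi = n_shore = 0
        for c in use:
            contig, pos = c.position.contig, c.position.pos
            if annotations.cgi.contains_point(contig, pos):
                n_cgi += 1
            elif _in_shore(annotations.cgi, contig, pos, shore_width):
                n_shore += 1
        rows.append({"clone": name, "n_cgi": n_cgi, "n_shore": n_shore})
    return pd.DataFrame(rows)


def tss_distance_profile(calls: Sequence[SNVCall], annotations: AnnotationSet,
                         bins: Sequence[int],
                         germline_calls: Optional[Sequence[SNVCall]] = None,
                         n_clones: int = 1, n_individuals: int = 1,
                         cpg_ct_only: bool = True) -> pd.DataFrame:
    """Histogram of strandless distances to the nearest TSS.

    ``bins`` are edges as for :func:`numpy.histogram` (right-open except the
    last). With ``germline_calls`` the per-bin ratio (calls per clone) /
    (germline calls per individual) is added; the germline denominator of a
    bin equal to zero yields NaN.
    """
    if not annotations.tss:
        raise ValueError("TSS track is empty")

    def _distances(cs: Sequence[SNVCall]) -> np.ndarray:
        out = []
        for c in cs:
            if cpg_ct_only and not c.is_cpg_ct:
                continue
            d = annotations.nearest_tss_distance(c.position.contig, c.position.pos)
            if d is not None:
                out.append(d)
        return np.array(out, dtype=np.int64)

    edges = np.asarray(bins, dtype=np.int64)
    hist, _ = np.histogram(_distances(calls), bins=edges)
    df = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "n_calls": hist,
        "per_clone": hist / n_clones,
    })
    if germline_calls is not None:
        ghist, _ = np.histogram(_distances(germline_calls), bins=edges)
        df["n_germline"] = ghist
        per_ind = ghist / n_individuals
        df["per_individual"] = per_ind
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio_to_germline"] = np.where(per_ind > 0,
                                               df["per_clone"] / per_ind, np.nan)
    return df


# ---------------------------------------------------------------------------
# Two-proportion Z-test
# ---------------------------------------------------------------------------

def z_test_two_proportions(x1: int, n1: int, x2: int, n2: int
                           ) -> tuple[float, float]:
    """Pooled two-proportion Z-test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(p̂ (1 - p̂) (1/n1 + 1/n2)) with p̂ the pooled
    proportion. Equal proportions (including the degenerate all-zero /
    all-one cases, where the pooled variance vanishes) give z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be > 0")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts outside [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if p1 == p2:
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p
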