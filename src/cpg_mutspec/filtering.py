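"""SNV identification filters, as composable predicates plus one pipeline.

Default thresholds: central base quality >= 30, mean surrounding quality
>= 15 over an 11-base window, gap+mismatch count <= 2, depth >= 20,
parental variant-allele reads <= 1, sister variant-allele reads <= 1,
VAF in the closed interval [0.35, 0.65], known variants / simple repeats /
homopolymers excluded. Acceptance is a pure conjunction of the enabled
predicates, so it is order-independent; only the report's attribution of a
rejected record to its *first* failing filter depends on the listed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from .core import GenomeSequence, SNVCall, VariantCandidate
from .spectrum import make_call

__all__ = [
    "FilterParams",
    "FilterReport",
    "MissingMetricError",
    "FILTER_ORDER",
    "apply_filters",
    "detect_homopolymer_flags",
]

#: reporting order of the filters
FILTER_ORDER = (
    "central_qual",
    "surround_qual",
    "gap_mismatch",
    "depth",
    "parental",
    "known",
    "sister",
    "simple_repeat",
    "homopolymer",
    "vaf",
)


class MissingMetricError(ValueError):
    """A filter needed a metric that the candidate does not carry."""

    def __init__(self, metric: str, candidate: VariantCandidate):
        self.metric = metric
        super().__init__(
            f"candidate at {candidate.position.contig}:{candidate.position.pos} "
            f"is missing required metric {metric!r}"
        )


@dataclass
class FilterParams:
    min_central_qual: float = 30.0
    min_surround_qual: float = 15.0
    window_length: int = 11
    max_gap_mismatch: int = 2
    min_depth: int = 20
    max_parental_alt: int = 1   # exclude when parental alt reads >= 2
    max_sister_alt: int = 1     # exclude when sister alt reads >= 2
    vaf_min: float = 0.35
    vaf_max: float = 0.65       # closed interval: 0.35 and 0.65 accepted
    exclude_known: bool = True
    exclude_sisters: bool = True  # OFF for shared-SNV analysis
    exclude_simple_repeat: bool = True
    homopolymer_min_run: int = 7

    def __post_init__(self):
        if not 0 <= self.vaf_min < self.vaf_max <= 1:
            raise ValueError(f"bad VAF bounds [{self.vaf_min}, {self.vaf_max}]")
        for name in ("min_central_qual", "min_surround_qual", "window_length",
                     "max_gap_mismatch", "min_depth", "max_parental_alt",
                     "max_sister_alt", "homopolymer_min_run"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _need(value, metric: str, cand: VariantCandidate):
    if value is None:
        raise MissingMetricError(metric, cand)
    return value


def _predicates(params: FilterParams) -> list[tuple[str, Callable[[VariantCandidate], bool]]]:
    """(name, fails) pairs in reporting order; ``fails(c)`` -> True = reject."""
    preds: list[tuple[str, Callable[[VariantCandidate], bool]]] = [
        ("central_qual",
         lambda c: _need(c.central_qual, "central_qual", c) < params.min_central_qual),
        ("surround_qual",
         lambda c: _need(c.surround_qual, "surround_qual", c) < params.min_surround_qual),
        ("gap_mismatch",
         lambda c: _need(c.gap_mismatch, "gap_mismatch", c) > params.max_gap_mismatch),
        ("depth",
         lambda c: _need(c.depth, "depth", c) < params.min_depth),
        ("parental",
         lambda c: _need(c.parental_alt_count, "parental_alt_count", c)
         > params.max_parental_alt),
    ]
    if params.exclude_known:
        preds.append(("known", lambda c: _need(c.known_variant, "known_variant", c)))
    if params.exclude_sisters:
        preds.append((
            "sister",
            lambda c: any(s > params.max_sister_alt
                          for s in _need(c.sister_alt_counts, "sister_alt_counts", c)),
        ))
    if params.exclude_simple_repeat:
        preds.append(("simple_repeat",
                      lambda c: _need(c.in_simple_repeat, "in_simple_repeat", c)))
        preds.append(("homopolymer",
                      lambda c: _need(c.in_homopolymer, "in_homopolymer", c)))
    preds.append((
        "vaf",
        lambda c: not (params.vaf_min
                       <= _need(c.alt_count, "alt_count", c)
                       / _need(c.depth, "depth", c)
                       <= params.vaf_max),
    ))
    return preds


@dataclass
class FilterReport:
    input_count: int
    accepted_count: int
    removals: dict[str, int]
    labels: list[Optional[str]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.input_count != self.accepted_count + sum(self.removals.values()):
            raise ValueError("report counts do not add up")

    def to_rows(self) -> list[dict]:
        rows = [{"filter": name, "removed": n} for name, n in self.removals.items()]
        rows.append({"filter": "(accepted)", "removed": self.accepted_count})
        return rows


def apply_filters(candidates: Sequence[VariantCandidate],
                  params: Optional[FilterParams] = None,
                  genome: Optional[GenomeSequence] = None,
                  ) -> tuple[list[SNVCall], FilterReport]:
    """Apply all enabled filters; return accepted calls and a report.

    When ``genome`` is supplied, accepted calls are classified against it
    (mutation class, 3'-neighbor, CpG status); otherwise classification
    fields beyond the collapsed class are left unset.
    """
    params = params or FilterParams()
    preds = _predicates(params)
    removals = {name: 0 for name, _ in preds}
    labels: list[Optional[str]] = []
    accepted: list[SNVCall] = []
    for cand in candidates:
        first_fail = None
        for name, fails in preds:
            if fails(cand):
                first_fail = name
                break
        labels.append(first_fail)
        if first_fail is not None:
            removals[first_fail] += 1
            continue
        if genome is not None:
            accepted.append(make_call(genome, cand.position, cand.ref_base,
                                      cand.alt_base, vaf=cand.vaf))
        else:
            accepted.append(SNVCall(position=cand.position, ref_base=cand.ref_base,
                                    alt_base=cand.alt_base, vaf=cand.vaf))
    report = FilterReport(input_count=len(candidates),
                          accepted_count=len(accepted),
                          removals=removals, labels=labels)
    return accepted, report


def detect_homopolymer_flags(genome: GenomeSequence,
                             candidates: Sequence[VariantCandidate],
                             min_run: int = 7) -> list[VariantCandidate]:
    """Return copies of the candidates with ``in_homopolymer`` set.

    A position is flagged iff the maximal single-base run containing it has
    length >= ``min_run`` (runs are measured on the reference sequence, so
    flags are invariant under reverse complement).
    """
    out = []
    for cand in candidates:
        seq = genome.contigs[cand.position.contig]
        i = cand.position.pos - 1
        base = seq[i]
        lo = i
        while lo > 0 and seq[lo - 1] == base:
            lo -= 1
        hi = i
        while hi + 1 < len(seq) and seq[hi + 1] == base:
            hi += 1
        out.append(replace(cand, in_homopolymer=(hi - lo + 1) >= min_run))
    return out
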