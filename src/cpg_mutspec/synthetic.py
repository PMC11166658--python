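"""Synthetic genomes, annotation tracks, mutation sets and clone families.

The genome model is a first-order Markov chain over bases constructed so
that (a) its stationary base composition matches the requested GC fraction
exactly and (b) the stationary CpG dinucleotide frequency equals
``cpg_obs_exp * p_C * p_G``. This is the single genomic property the
downstream abundance normalization depends on.

All distributional choices here are stand-ins for empirical data and are
documented as such; every sampler is driven by an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotations import AnnotationSet, Transcript, TSSRecord
from .core import COMPLEMENT, GenomeSequence, GenomicPosition, SNVCall, VariantCandidate
from .filtering import FILTER_ORDER, FilterParams, _predicates
from .intervals import Interval, IntervalTrack
from .spectrum import BASES, encode, make_call

__all__ = [
    "RateTable",
    "MetricNoise",
    "CloneFamilyConfig",
    "CloneFamily",
    "FamilyTruthRecord",
    "RegionBoost",
    "transition_matrix",
    "generate_genome",
    "generate_annotations",
    "simulate_mutations",
    "simulate_clone_family",
    "clone_call_keys_vs_reference",
]

_PYR = ("C", "T")
_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}


# ---------------------------------------------------------------------------
# Rate tables
# ---------------------------------------------------------------------------

class RateTable:
    """Relative per-context mutation rates keyed by (pyr ref, 3'-neighbor, alt)."""

    def __init__(self, rates: dict[tuple[str, str, str], float]):
        clean: dict[tuple[str, str, str], float] = {}
        for (ref, nb, alt), rate in rates.items():
            if ref not in _PYR or nb not in BASES or alt not in _ALTS[ref]:
                raise ValueError(f"invalid rate key ({ref},{nb},{alt})")
            if rate < 0:
                raise ValueError(f"negative rate for ({ref},{nb},{alt})")
            clean[(ref, nb, alt)] = float(rate)
        if not any(v > 0 for v in clean.values()):
            raise ValueError("rate table has no positive rate")
        self.rates = clean

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return self.rates.get(key, 0.0)

    def items(self):
        return self.rates.items()

    @classmethod
    def uniform(cls, rate: float = 1.0) -> "RateTable":
        return cls({(ref, nb, alt): rate
                    for ref in _PYR for nb in BASES for alt in _ALTS[ref]})

    @classmethod
    def cpg_ct_boosted(cls, fold: float, base_rate: float = 1.0) -> "RateTable":
        """Uniform rates with the CpG C>T cell multiplied by ``fold``."""
        table = {(ref, nb, alt): base_rate
                 for ref in _PYR for nb in BASES for alt in _ALTS[ref]}
        table[("C", "G", "T")] = base_rate * fold
        return cls(table)

    def as_matrix(self) -> np.ndarray:
        """Rates as an (8 contexts x 4 alt codes) array.

        Context index = (0 for C / 1 for T) * 4 + neighbor code; alt column
        indexed by base code with zeros where alt == ref.
        """
        mat = np.zeros((8, 4), dtype=float)
        for (ref, nb, alt), rate in self.rates.items():
            row = (0 if ref == "C" else 1) * 4 + BASES.index(nb)
            mat[row, BASES.index(alt)] = rate
        return mat


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def transition_matrix(gc_fraction: float, cpg_obs_exp: float) -> np.ndarray:
    """Markov transition matrix (A,C,G,T order) with exact stationary targets.

    The stationary distribution is exactly ``(p_A, p_C, p_G, p_T)`` with
    ``p_C = p_G = gc/2`` and the stationary CpG frequency is exactly
    ``cpg_obs_exp * p_C * p_G``.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if cpg_obs_exp <= 0:
        raise ValueError("cpg_observed_expected must be > 0")
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    p = np.array([p_at, p_gc, p_gc, p_at])  # A, C, G, T
    t = cpg_obs_exp
    bound = min(1.0 / p[1], 1.0 / p[2])
    if t >= bound:
        raise ValueError(
            f"infeasible (gc={gc_fraction}, o/e={cpg_obs_exp}): "
            f"observed/expected must be < {bound:.4g} at this GC fraction"
        )
    P = np.zeros((4, 4))
    # row C: P(C->G) = t * p_G, remainder proportional to p
    P[1, 2] = t * p[2]
    for y in (0, 1, 3):
        P[1, y] = p[y] * (1.0 - t * p[2]) / (1.0 - p[2])
    # rows A, G, T: column-G balance then proportional remainder
    g0 = p[2] * (1.0 - t * p[1]) / (1.0 - p[1])
    for x in (0, 2, 3):
        P[x, 2] = g0
        for y in (0, 1, 3):
            P[x, y] = p[y] * (1.0 - g0) / (1.0 - p[2])
    assert np.allclose(P.sum(axis=1), 1.0)
    assert np.allclose(p @ P, p)
    return P


def _sample_chain(length: int, P: np.ndarray, p0: np.ndarray,
                  rng: np.random.Generator) -> str:
    # rows A, G, T of P are identical by construction; only "previous base
    # was C" matters, so two cumulative rows suffice.
    cum_c = np.cumsum(P[1]).tolist()
    cum_nc = np.cumsum(P[0]).tolist()
    c0, c1, c2 = cum_c[0], cum_c[1], cum_c[2]
    n0, n1, n2 = cum_nc[0], cum_nc[1], cum_nc[2]
    u = rng.random(length).tolist()
    first = int(np.searchsorted(np.cumsum(p0), u[0], side="right"))
    out = np.empty(length, dtype=np.uint8)
    out[0] = first
    is_c = first == 1
    for i in range(1, length):
        x = u[i]
        if is_c:
            s = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        else:
            s = 0 if x < n0 else 1 if x < n1 else 2 if x < n2 else 3
        out[i] = s
        is_c = s == 1
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def generate_genome(length: int, gc_fraction: float = 0.5,
                    cpg_obs_exp: float = 1.0, n_contigs: int = 1,
                    seed: int = 0) -> GenomeSequence:
    """Generate a random genome with controlled GC and CpG observed/expected."""
    if length < n_contigs or n_contigs < 1:
        raise ValueError("need length >= n_contigs >= 1")
    P = transition_matrix(gc_fraction, cpg_obs_exp)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    p0 = np.array([p_at, p_gc, p_gc, p_at])
    rng = np.random.default_rng(seed)
    base_len = length // n_contigs
    contigs = {}
    for i in range(n_contigs):
        clen = base_len + (length - base_len * n_contigs if i == 0 else 0)
        contigs[f"chr{i + 1}"] = _sample_chain(clen, P, p0, rng)
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

DEFAULT_SUBFAMILY_MIX = {
    "AluJb": 0.15, "AluJo": 0.10,
    "AluSx": 0.20, "AluSp": 0.10,
    "AluY": 0.30, "AluYa5": 0.10, "AluYb8": 0.05,
}

_TRACK_INTERVAL_LEN = {"sine": 300, "line": 3000, "ltr": 1000,
                       "cgi": 600, "dmr": 800, "simple_repeat": 60}


def _place_nonoverlapping(contig_len: int, n: int, iv_len: int,
                          rng: np.random.Generator,
                          occupied: list[tuple[int, int]],
                          preferred_starts: Optional[Sequence[int]] = None,
                          ) -> list[tuple[int, int]]:
    """Place ``n`` intervals of ``iv_len`` without overlapping ``occupied``."""
    import bisect
    occ = sorted(occupied)
    placed = []
    if preferred_starts is not None:
        pool = list(preferred_starts)
    else:
        pool = None
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"genome too short to place {n} intervals of length {iv_len}"
            )
        if pool is not None:
            if not pool:
                raise ValueError(
                    f"not enough candidate windows to place {n} intervals"
                )
            start = pool.pop(0)
        else:
            start = int(rng.integers(0, max(1, contig_len - iv_len)))
        end = start + iv_len
        if end > contig_len:
            continue
        i = bisect.bisect_left(occ, (start, end))
        ok = True
        if i > 0 and occ[i - 1][1] > start:
            ok = False
        if ok and i < len(occ) and occ[i][0] < end:
            ok = False
        if ok:
            occ.insert(i, (start, end))
            placed.append((start, end))
    return placed


def _cpg_rich_windows(seq: str, window: int) -> list[int]:
    """Non-overlapping window starts ranked by CpG density (descending)."""
    codes = encode(seq)
    is_cg = (codes[:-1] == 1) & (codes[1:] == 2)
    n_win = len(seq) // window
    if n_win == 0:
        return []
    trimmed = is_cg[:n_win * window - 1]
    dens = np.add.reduceat(np.append(trimmed, 0).astype(np.int64),
                           np.arange(0, n_win * window, window))
    order = np.argsort(-dens, kind="stable")
    return [int(i) * window for i in order]


def generate_annotations(genome: GenomeSequence,
                         fractions: Optional[dict[str, float]] = None,
                         subfamily_mix: Optional[dict[str, float]] = None,
                         cpg_bias_in_sine: bool = False,
                         n_genes: int = 0,
                         seed: int = 0) -> AnnotationSet:
    """Generate non-overlapping annotation tracks over a genome.

    ``fractions`` maps track names (``sine``, ``line``, ``ltr``, ``cgi``,
    ``dmr``, ``simple_repeat``) to target genome fractions. SINE intervals
    carry subfamily labels drawn from ``subfamily_mix`` and, when
    ``cpg_bias_in_sine`` is set, are preferentially placed on the most
    CpG-dense windows (mimicking Alu CpG-richness).
    """
    fractions = dict(fractions or {})
    unknown = set(fractions) - set(_TRACK_INTERVAL_LEN)
    if unknown:
        raise ValueError(f"unknown track(s): {sorted(unknown)}")
    if sum(fractions.values()) > 1:
        raise ValueError("track fractions sum > 1")
    mix = dict(subfamily_mix or DEFAULT_SUBFAMILY_MIX)
    mix_names = list(mix)
    mix_p = np.array([mix[k] for k in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()
    rng = np.random.default_rng(seed)

    repeat_ivs: list[Interval] = []
    single_tracks: dict[str, list[Interval]] = {"cgi": [], "dmr": [], "simple_repeat": []}

    for contig, seq in genome.contigs.items():
        clen = len(seq)
        occupied_repeats: list[tuple[int, int]] = []
        # SINEs first so the CpG-rich bias is honored before space fills up.
        for track, klass in (("sine", "SINE"), ("line", "LINE"), ("ltr", "LTR")):
            frac = fractions.get(track, 0.0)
            if frac <= 0:
                continue
            iv_len = _TRACK_INTERVAL_LEN[track]
            if iv_len > clen:
                raise ValueError(
                    f"genome too short: contig {contig} ({clen} bp) cannot "
                    f"hold a {track} interval of {iv_len} bp"
                )
            n = int(round(frac * clen / iv_len))
            preferred = None
            if track == "sine" and cpg_bias_in_sine:
                preferred = _cpg_rich_windows(seq, iv_len)
            placed = _place_nonoverlapping(clen, n, iv_len, rng,
                                           occupied_repeats, preferred)
            occupied_repeats.extend(placed)
            for start, end in placed:
                if klass == "SINE":
                    name = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
                elif klass == "LINE":
                    name = "L1"
                else:
                    name = "ERVL"
                repeat_ivs.append(Interval(contig, start, end, name=name, label=klass))
        for track in ("cgi", "dmr", "simple_repeat"):
            frac = fractions.get(track, 0.0)
            if frac <= 0:
                continue
            iv_len = _TRACK_INTERVAL_LEN[track]
            n = int(round(frac * clen / iv_len))
            placed = _place_nonoverlapping(clen, n, iv_len, rng, [])
            for start, end in placed:
                single_tracks[track].append(Interval(contig, start, end))

    transcripts: list[Transcript] = []
    tss: list[TSSRecord] = []
    if n_genes:
        per_contig = _split_counts(n_genes, [len(s) for s in genome.contigs.values()],
                                   rng)
        for (contig, seq), n in zip(genome.contigs.items(), per_contig):
            occupied: list[tuple[int, int]] = []
            for g in range(n):
                tx = _random_transcript(f"{contig}_tx{g + 1}", contig, len(seq),
                                        rng, occupied)
                if tx is None:
                    raise ValueError("genome too short for requested gene count")
                transcripts.append(tx)
                occupied.append(tx.span)
                pos = tx.span[0] + 1 if tx.strand == "+" else tx.span[1]
                tss.append(TSSRecord(contig=contig, pos=pos, strand=tx.strand,
                                     name=tx.transcript_id))

    ann = AnnotationSet(
        repeats=IntervalTrack(repeat_ivs),
        cgi=IntervalTrack(single_tracks["cgi"]),
        tss=tss,
        dmr=IntervalTrack(single_tracks["dmr"]),
        simple_repeats=IntervalTrack(single_tracks["simple_repeat"]),
        transcripts=transcripts,
    )
    ann.validate(genome)
    return ann


def _split_counts(total: int, weights: Sequence[int],
                  rng: np.random.Generator) -> list[int]:
    w = np.array(weights, dtype=float)
    return list(rng.multinomial(total, w / w.sum()))


def _random_transcript(tid: str, contig: str, contig_len: int,
                       rng: np.random.Generator,
                       occupied: list[tuple[int, int]]) -> Optional[Transcript]:
    for _ in range(200):
        n_exons = int(rng.integers(1, 4))
        cds_len = 3 * int(rng.integers(30, 120))
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        exon_lens = np.diff([0, *map(int, cuts), cds_len])
        intron_lens = rng.integers(50, 300, size=n_exons - 1)
        span_len = int(exon_lens.sum() + intron_lens.sum())
        if span_len + 2 >= contig_len:
            continue
        start = int(rng.integers(0, contig_len - span_len))
        end = start + span_len
        if any(s < end and start < e for s, e in occupied):
            continue
        exons = []
        cur = start
        for i, el in enumerate(exon_lens):
            exons.append((cur, cur + int(el)))
            cur += int(el)
            if i < n_exons - 1:
                cur += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        return Transcript(transcript_id=tid, contig=contig, strand=strand,
                          exons=exons)
    return None


# ---------------------------------------------------------------------------
# Mutation simulation
# ---------------------------------------------------------------------------

@dataclass
class RegionBoost:
    """Multiply mutation rates inside a track by ``factor``.

    With ``cpg_ct_only`` the boost applies only to the CpG C>T category
    (sites whose collapsed context is C with 3'-neighbor G, alt T).
    """

    track: IntervalTrack
    factor: float
    cpg_ct_only: bool = True


def _site_contexts(genome: GenomeSequence):
    """Vectorized per-position collapsed context over all contigs.

    Returns (contig names, positions (1-based), context index 0..7, and the
    plus-strand base code) for every classifiable position.
    """
    names, positions, contexts, plus_codes = [], [], [], []
    for contig, seq in genome.contigs.items():
        b = encode(seq).astype(np.int64)
        n = len(b)
        ctx = np.full(n, -1, dtype=np.int64)
        pyr = (b == 1) | (b == 3)
        pur = (b == 0) | (b == 2)
        # pyrimidine on plus strand: neighbor is the next base
        idx = np.nonzero(pyr[:-1] & (b[1:] < 4))[0]
        ref_idx = (b[idx] == 3).astype(np.int64)  # 0 for C, 1 for T
        ctx[idx] = ref_idx * 4 + b[idx + 1]
        # purine: collapsed to minus strand; neighbor = comp(previous base)
        idx = np.nonzero(pur[1:] & (b[:-1] < 4))[0] + 1
        ref_idx = (b[idx] == 0).astype(np.int64)  # A -> T(1), G -> C(0)
        comp_prev = 3 - b[idx - 1]
        ctx[idx] = ref_idx * 4 + comp_prev
        valid = ctx >= 0
        names.append(contig)
        positions.append(np.nonzero(valid)[0] + 1)
        contexts.append(ctx[valid])
        plus_codes.append(b[valid])
    return names, positions, contexts, plus_codes


def simulate_mutations(genome: GenomeSequence, rate_table: RateTable,
                       n_total: int, seed: int = 0,
                       boost: Optional[RegionBoost] = None) -> list[SNVCall]:
    """Draw mutation sites without replacement with probability ∝ rate(context).

    Returns classified truth calls (VAF fixed at 0.5), sorted by position.
    Sampling uses Gumbel top-k, equivalent to successive weighted draws
    without replacement.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if n_total == 0:
        return []
    rng = np.random.default_rng(seed)
    R = rate_table.as_matrix()
    site_w = R.sum(axis=1)

    names, positions, contexts, plus_codes = _site_contexts(genome)
    all_w, boosted_masks = [], []
    cpg_rate = rate_table[("C", "G", "T")]
    for contig, pos, ctx in zip(names, positions, contexts):
        w = site_w[ctx]
        boosted = np.zeros(len(pos), dtype=bool)
        if boost is not None and boost.factor != 1.0:
            in_track = boost.track.point_mask(contig, pos)
            if boost.cpg_ct_only:
                boosted = in_track & (ctx == 2)  # context (C, G)
                w = w + boosted * (boost.factor - 1.0) * cpg_rate
            else:
                boosted = in_track
                w = np.where(in_track, w * boost.factor, w)
        all_w.append(w)
        boosted_masks.append(boosted)

    w = np.concatenate(all_w)
    eligible = w > 0
    n_eligible = int(eligible.sum())
    if n_total > n_eligible:
        raise ValueError(
            f"n_total={n_total} exceeds {n_eligible} eligible sites"
        )
    keys = np.full(len(w), -np.inf)
    idx_e = np.nonzero(eligible)[0]
    keys[idx_e] = np.log(w[idx_e]) + rng.gumbel(size=len(idx_e))
    chosen = np.argpartition(-keys, n_total - 1)[:n_total]

    contig_of = np.concatenate([
        np.full(len(p), i, dtype=np.int64) for i, p in enumerate(positions)
    ])
    offsets = np.cumsum([0, *(len(p) for p in positions)])
    pos_flat = np.concatenate(positions)
    ctx_flat = np.concatenate(contexts)
    boosted_flat = np.concatenate(boosted_masks)

    chosen = chosen[np.lexsort((pos_flat[chosen], contig_of[chosen]))]
    calls = []
    for j in chosen:
        contig = names[int(contig_of[j])]
        pos = int(pos_flat[j])
        ctx = int(ctx_flat[j])
        probs = R[ctx].copy()
        if boost is not None and boosted_flat[j] and boost.cpg_ct_only:
            probs[3] *= boost.factor  # alt T at the CpG C context
        probs = probs / probs.sum()
        alt_pyr = BASES[int(rng.choice(4, p=probs))]
        ref_plus = genome.base(contig, pos)
        alt_plus = alt_pyr if ref_plus in "CT" else COMPLEMENT[alt_pyr]
        calls.append(make_call(genome, GenomicPosition(contig, pos),
                               ref_plus, alt_plus, vaf=0.5))
    return calls


# ---------------------------------------------------------------------------
# Clone families
# ---------------------------------------------------------------------------

@dataclass
class MetricNoise:
    """Read-metric noise model; all-zero spreads give deterministic metrics."""

    depth_mean: float = 40.0
    depth_sd: float = 0.0
    central_qual_mean: float = 38.0
    central_qual_sd: float = 0.0
    surround_qual_mean: float = 30.0
    surround_qual_sd: float = 0.0
    gap_mismatch_lambda: float = 0.0


@dataclass
class CloneFamilyConfig:
    """Design of a sister-clone family with known shared/private structure."""

    n_clones: int
    n_private_per_clone: int = 0
    shared: dict[tuple[int, ...], int] = field(default_factory=dict)
    n_preexisting_subclonal: int = 0
    preexisting_cell_fraction: float = 0.3
    parental_depth: int = 100
    vaf_alpha: float = 50.0
    vaf_beta: float = 50.0
    metric_noise: MetricNoise = field(default_factory=MetricNoise)
    fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for name in ("n_private_per_clone", "n_preexisting_subclonal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.preexisting_cell_fraction <= 1:
            if self.n_preexisting_subclonal:
                raise ValueError("preexisting_cell_fraction must be in (0, 1]")
        for subset, count in self.shared.items():
            if count < 0:
                raise ValueError("shared counts must be >= 0")
            if len(subset) < 2:
                raise ValueError(f"shared subset {subset} needs >= 2 clones")
            if any(not 0 <= i < self.n_clones for i in subset):
                raise ValueError(f"clone index out of range in subset {subset}")
        if not 0 <= self.fail_fraction <= 1:
            raise ValueError("fail_fraction must be in [0, 1]")


@dataclass
class FamilyTruthRecord:
    clone: int
    contig: str
    pos: int
    ref: str
    alt: str
    origin: str                 # private | shared | preexisting
    subset: tuple[int, ...]     # clones carrying the variant
    expected_fail: Optional[str]  # first failing filter, or None


@dataclass
class CloneFamily:
    clones: list[list[VariantCandidate]]
    truth: list[FamilyTruthRecord]
    parental_alt: dict[tuple[str, int, str, str], int]
    config: CloneFamilyConfig

    def truth_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "clone": t.clone, "contig": t.contig, "pos": t.pos,
            "ref": t.ref, "alt": t.alt, "origin": t.origin,
            "subset": ",".join(map(str, t.subset)),
            "expected_fail": t.expected_fail or "",
        } for t in self.truth])


_INJECTABLE_FAILS = ("central_qual", "surround_qual", "gap_mismatch", "depth",
                     "parental", "known", "simple_repeat", "vaf")


def simulate_clone_family(genome: GenomeSequence, rate_table: RateTable,
                          config: CloneFamilyConfig,
                          filter_params: Optional[FilterParams] = None,
                          ) -> CloneFamily:
    """Simulate per-clone candidate lists with a complete truth ledger.

    Shared mutations are injected into their designated clone subsets;
    pre-existing sub-clonal variants get parental allele counts drawn
    ``Binomial(parental_depth, cell_fraction / 2)`` and are carried by a
    random clone subset (each clone independently with probability equal to
    the cell fraction, at least one carrier). ``expected_fail`` labels are
    evaluated on the final field values of each record under
    ``filter_params``, so the ledger is exact by construction.
    """
    params = filter_params or FilterParams()
    rng = np.random.default_rng(config.seed)
    noise = config.metric_noise

    n_shared = sum(config.shared.values())
    n_needed = (n_shared + config.n_preexisting_subclonal
                + config.n_clones * config.n_private_per_clone)
    sites = simulate_mutations(genome, rate_table, n_needed,
                               seed=int(rng.integers(2**31)))
    order = rng.permutation(len(sites))
    sites = [sites[i] for i in order]

    # variant -> (origin, carriers)
    assignments: list[tuple[SNVCall, str, tuple[int, ...]]] = []
    cursor = 0
    for subset, count in sorted(config.shared.items()):
        for _ in range(count):
            assignments.append((sites[cursor], "shared", tuple(sorted(subset))))
            cursor += 1
    preexisting_sites = []
    for _ in range(config.n_preexisting_subclonal):
        carriers = tuple(i for i in range(config.n_clones)
                         if rng.random() < config.preexisting_cell_fraction)
        if not carriers:
            carriers = (int(rng.integers(config.n_clones)),)
        assignments.append((sites[cursor], "preexisting", carriers))
        preexisting_sites.append(sites[cursor].key)
        cursor += 1
    for clone in range(config.n_clones):
        for _ in range(config.n_private_per_clone):
            assignments.append((sites[cursor], "private", (clone,)))
            cursor += 1

    parental_alt: dict[tuple[str, int, str, str], int] = {}
    for call, origin, _ in assignments:
        if origin == "preexisting":
            parental_alt[call.key] = int(rng.binomial(
                config.parental_depth, config.preexisting_cell_fraction / 2.0))

    def _metric(mean: float, sd: float) -> float:
        return float(rng.normal(mean, sd)) if sd > 0 else mean

    min_run = params.homopolymer_min_run
    clones: list[list[VariantCandidate]] = [[] for _ in range(config.n_clones)]
    truth: list[FamilyTruthRecord] = []
    preds = _predicates(params)

    for call, origin, carriers in assignments:
        contig, pos, ref, alt = call.key
        for clone in carriers:
            depth = max(1, int(round(_metric(noise.depth_mean, noise.depth_sd))))
            vaf = float(rng.beta(config.vaf_alpha, config.vaf_beta))
            alt_count = min(depth, max(0, int(round(depth * vaf))))
            sisters = []
            for other in range(config.n_clones):
                if other == clone:
                    continue
                if other in carriers:
                    sisters.append(int(rng.binomial(
                        max(1, int(noise.depth_mean)), 0.5)))
                else:
                    sisters.append(0)
            cand = VariantCandidate(
                position=GenomicPosition(contig, pos),
                ref_base=ref, alt_base=alt,
                depth=depth, alt_count=alt_count,
                central_qual=_metric(noise.central_qual_mean, noise.central_qual_sd),
                surround_qual=_metric(noise.surround_qual_mean, noise.surround_qual_sd),
                gap_mismatch=(int(rng.poisson(noise.gap_mismatch_lambda))
                              if noise.gap_mismatch_lambda > 0 else 0),
                parental_alt_count=parental_alt.get(call.key, 0),
                sister_alt_counts=tuple(sisters),
                known_variant=False,
                in_simple_repeat=False,
                in_homopolymer=_in_homopolymer(genome, contig, pos, min_run),
            )
            if config.fail_fraction > 0 and rng.random() < config.fail_fraction:
                _inject_failure(cand, rng, params)
            expected_fail = None
            for name, fails in preds:
                if fails(cand):
                    expected_fail = name
                    break
            clones[clone].append(cand)
            truth.append(FamilyTruthRecord(
                clone=clone, contig=contig, pos=pos, ref=ref, alt=alt,
                origin=origin, subset=carriers, expected_fail=expected_fail))

    for clone_list in clones:
        clone_list.sort(key=lambda c: (c.position.contig, c.position.pos))
    return CloneFamily(clones=clones, truth=truth, parental_alt=parental_alt,
                       config=config)


def _in_homopolymer(genome: GenomeSequence, contig: str, pos: int,
                    min_run: int) -> bool:
    seq = genome.contigs[contig]
    i = pos - 1
    base = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return (hi - lo + 1) >= min_run


def _inject_failure(cand: VariantCandidate, rng: np.random.Generator,
                    params: FilterParams) -> None:
    which = _INJECTABLE_FAILS[int(rng.integers(len(_INJECTABLE_FAILS)))]
    if which == "central_qual":
        cand.central_qual = params.min_central_qual - 1.0
    elif which == "surround_qual":
        cand.surround_qual = params.min_surround_qual - 1.0
    elif which == "gap_mismatch":
        cand.gap_mismatch = params.max_gap_mismatch + 1
    elif which == "depth":
        cand.depth = params.min_depth - 1
        cand.alt_count = min(cand.alt_count, cand.depth)
    elif which == "parental":
        cand.parental_alt_count = params.max_parental_alt + 1
    elif which == "known":
        cand.known_variant = True
    elif which == "simple_repeat":
        cand.in_simple_repeat = True
    elif which == "vaf":
        cand.alt_count = max(0, int(cand.depth * (params.vaf_min - 0.15)))


def clone_call_keys_vs_reference(family: CloneFamily, clone: int,
                                 reference: Optional[int] = None,
                                 min_control_alt: int = 2,
                                 ) -> set[tuple[str, int, str, str]]:
    """Variant keys called in ``clone`` against a control sample.

    ``reference=None`` uses the parental population (variants with
    >= ``min_control_alt`` parental alt reads are subtracted). An integer
    selects a sister clone as control: variants the sister also carries are
    subtracted, mirroring reference-swap calling.
    """
    if not 0 <= clone < family.config.n_clones:
        raise ValueError("clone index out of range")
    sister_keys = (None if reference is None else
                   {c.key for c in family.clones[reference]})
    out = set()
    for cand in family.clones[clone]:
        if reference is None:
            if (cand.parental_alt_count or 0) >= min_control_alt:
                continue
        else:
            if reference == clone:
                continue
            if cand.key in sister_keys:
                continue
        out.add(cand.key)
    return out
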