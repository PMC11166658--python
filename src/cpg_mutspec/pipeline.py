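"""End-to-end orchestration: config, staged run, TSV report bundle, manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .annotations import AnnotationSet
from .coding import annotate_coding, summarize_effects
from .core import GenomeSequence
from .enrichment import (assign_regions, cgi_shore_counts, dmr_ratio,
                         retrotransposon_rates, tss_distance_profile)
from .filtering import FilterParams, apply_filters, detect_homopolymer_flags
from .sister import shared_snvs
from .spectrum import build_spectrum, cpg_partition
from .synthetic import (CloneFamilyConfig, MetricNoise, RateTable,
                        generate_annotations, generate_genome,
                        simulate_clone_family)

logger = logging.getLogger(__name__)

STAGES = ("filter", "spectrum", "sister", "enrich", "coding")


@dataclass
class PipelineConfig:
    """Serializable run configuration; a run is reproducible from it alone."""

    genome: Optional[str] = None
    clone_vcfs: dict[str, str] = field(default_factory=dict)
    repeats: Optional[str] = None
    cgi: Optional[str] = None
    tss: Optional[str] = None
    dmr: Optional[str] = None
    simple_repeats: Optional[str] = None
    cds: Optional[str] = None
    germline_vcf: Optional[str] = None
    blacklist: Optional[str] = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    simulate: Optional[dict] = None   # synthetic-mode parameters
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fp = raw.pop("filter_params", None)
        cfg = cls(**raw)
        if fp:
            cfg.filter_params = FilterParams(**fp)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the staged analysis and write a TSV report bundle + manifest.

    Stages run in order filter -> spectrum -> sister -> enrich -> coding;
    stages missing their inputs (e.g. no DMR track) are skipped with a log
    message. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }

    genome, annotations, clone_candidates = _load_inputs(config, manifest)

    blacklist = None
    if config.blacklist:
        blacklist = cio.read_bed_track(config.blacklist)

    # ---- filter ---------------------------------------------------------
    clone_calls: dict[str, list] = {}
    if "filter" in config.stages:
        try:
            rows = []
            for name, candidates in clone_candidates.items():
                candidates = detect_homopolymer_flags(
                    genome, candidates,
                    min_run=config.filter_params.homopolymer_min_run)
                if blacklist is not None:
                    candidates = [c for c in candidates
                                  if not blacklist.contains_point(
                                      c.position.contig, c.position.pos)]
                accepted, report = apply_filters(candidates, config.filter_params,
                                                 genome)
                clone_calls[name] = accepted
                for row in report.to_rows():
                    rows.append({"clone": name, **row})
                cio.write_calls_vcf(accepted, outdir / f"calls.{name}.vcf",
                                    genome)
            pd.DataFrame(rows).to_csv(outdir / "filter_report.tsv", sep="\t",
                                      index=False)
            manifest["stages"]["filter"] = {
                "in": {n: len(c) for n, c in clone_candidates.items()},
                "out": {n: len(c) for n, c in clone_calls.items()},
            }
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError("filter", "applying filters", exc) from exc
    else:
        logger.info("filter stage skipped")

    all_calls = [c for calls in clone_calls.values() for c in calls]

    # ---- spectrum -------------------------------------------------------
    if "spectrum" in config.stages and clone_calls:
        try:
            table = build_spectrum(genome, all_calls)
            table.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
            part_rows = []
            for name, calls in clone_calls.items():
                p = cpg_partition(calls)
                part_rows.append({"clone": name, "n_total": p.n_total,
                                  "n_ct_cpg": p.n_ct_cpg,
                                  "n_ct_noncpg": p.n_ct_noncpg,
                                  "pct_ct_cpg": p.pct_ct_cpg,
                                  "pct_ct_noncpg": p.pct_ct_noncpg})
            pd.DataFrame(part_rows).to_csv(outdir / "cpg_partition.tsv",
                                           sep="\t", index=False)
            manifest["stages"]["spectrum"] = {
                "n_classified": table.n_classified,
                "n_excluded": table.n_excluded,
            }
        except Exception as exc:
            raise StageError("spectrum", "building spectrum", exc) from exc

    # ---- sister ---------------------------------------------------------
    if "sister" in config.stages and len(clone_calls) >= 2:
        try:
            result = shared_snvs(clone_calls)
            result.matrix_frame().to_csv(outdir / "shared_matrix.tsv", sep="\t")
            manifest["stages"]["sister"] = {
                "n_shared_variants": len(result.shared_variants),
                "shared_fraction_unique": result.shared_fraction_unique,
                "shared_fraction_instances": result.shared_fraction_instances,
            }
        except Exception as exc:
            raise StageError("sister", "shared-SNV analysis", exc) from exc
    elif "sister" in config.stages:
        logger.info("sister stage skipped: fewer than 2 clones")

    # ---- enrich ---------------------------------------------------------
    if "enrich" in config.stages and clone_calls:
        try:
            assignment = assign_regions(all_calls, annotations)
            assignment.table.to_csv(outdir / "region_assignment.tsv", sep="\t",
                                    index=False)
            manifest["stages"]["enrich"] = {
                "compartments": assignment.compartment_counts}
            if annotations.repeats:
                retrotransposon_rates(all_calls, annotations).to_csv(
                    outdir / "retrotransposon_rates.tsv", sep="\t", index=False)
            else:
                logger.info("repeat statistics skipped: no repeat track")
            if annotations.dmr:
                r = dmr_ratio(all_calls, annotations, genome)
                pd.DataFrame([asdict(r)]).to_csv(outdir / "dmr_ratio.tsv",
                                                 sep="\t", index=False)
            else:
                logger.info("DMR ratio skipped: no DMR track")
            if annotations.cgi:
                cgi_shore_counts(clone_calls, annotations).to_csv(
                    outdir / "cgi_shore.tsv", sep="\t", index=False)
            else:
                logger.info("CGI/shore counts skipped: no CGI track")
            if annotations.tss:
                bins = [0, 1000, 2000, 5000, 10000, 50000, 10**9]
                tss_distance_profile(all_calls, annotations, bins).to_csv(
                    outdir / "tss_distance.tsv", sep="\t", index=False)
            else:
                logger.info("TSS profile skipped: no TSS track")
        except Exception as exc:
            raise StageError("enrich", "enrichment statistics", exc) from exc

    # ---- coding ---------------------------------------------------------
    if "coding" in config.stages and clone_calls:
        try:
            if annotations.transcripts:
                effects = annotate_coding(all_calls, annotations, genome)
                pd.DataFrame([asdict(e) for e in effects]).to_csv(
                    outdir / "coding_effects.tsv", sep="\t", index=False)
                summary = summarize_effects(effects)
                manifest["stages"]["coding"] = {
                    "n_total": summary.n_total,
                    "ratio": list(summary.ratio),
                    "arg_fraction_pct": summary.arg_fraction_pct,
                }
            else:
                logger.info("coding stage skipped: no CDS track")
        except Exception as exc:
            raise StageError("coding", "coding annotation", exc) from exc

    # conservation check across the bundle
    if "spectrum" in manifest["stages"] and "enrich" in manifest["stages"]:
        n_spec = (manifest["stages"]["spectrum"]["n_classified"]
                  + manifest["stages"]["spectrum"]["n_excluded"])
        n_comp = sum(manifest["stages"]["enrich"]["compartments"].values())
        if n_spec != len(all_calls) or n_comp != len(all_calls):
            raise StageError("report", "conservation check",
                             ValueError("stage counts disagree"))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_inputs(config: PipelineConfig, manifest: dict):
    """Load (or simulate) genome, annotations and per-clone candidates."""
    if config.simulate is not None:
        return _simulate_inputs(config, manifest)
    if config.genome is None:
        raise ValueError("config needs either a genome path or a simulate block")
    genome = cio.read_genome(config.genome)
    manifest["inputs"]["genome"] = _sha256(config.genome)
    annotations = cio.read_annotations(
        repeats=config.repeats, cgi=config.cgi, tss=config.tss, dmr=config.dmr,
        simple_repeats=config.simple_repeats, cds=config.cds, genome=genome)
    for name in ("repeats", "cgi", "tss", "dmr", "simple_repeats", "cds"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = _sha256(path)
    clone_candidates = {}
    for name, path in config.clone_vcfs.items():
        clone_candidates[name] = cio.read_variants(path, genome)
        manifest["inputs"][f"vcf:{name}"] = _sha256(path)
    return genome, annotations, clone_candidates


def _simulate_inputs(config: PipelineConfig, manifest: dict):
    sim = dict(config.simulate or {})
    genome = generate_genome(
        length=int(sim.get("genome_length", 200_000)),
        gc_fraction=float(sim.get("gc_fraction", 0.45)),
        cpg_obs_exp=float(sim.get("cpg_obs_exp", 0.8)),
        n_contigs=int(sim.get("n_contigs", 1)),
        seed=config.seed,
    )
    annotations = generate_annotations(
        genome,
        fractions=sim.get("fractions", {"sine": 0.08, "line": 0.05, "ltr": 0.02,
                                        "cgi": 0.02, "dmr": 0.03,
                                        "simple_repeat": 0.005}),
        n_genes=int(sim.get("n_genes", 10)),
        seed=config.seed + 1,
    )
    rate_table = RateTable.cpg_ct_boosted(float(sim.get("cpg_ct_fold", 10.0)))
    fam_cfg = CloneFamilyConfig(
        n_clones=int(sim.get("n_clones", 3)),
        n_private_per_clone=int(sim.get("n_private_per_clone", 100)),
        shared={tuple(k): v for k, v in (sim.get("shared") or {}).items()},
        metric_noise=MetricNoise(**(sim.get("metric_noise") or {})),
        fail_fraction=float(sim.get("fail_fraction", 0.0)),
        seed=config.seed + 2,
    )
    family = simulate_clone_family(genome, rate_table, fam_cfg,
                                   config.filter_params)
    manifest["inputs"]["simulate"] = {
        k: ({",".join(map(str, s)): n for s, n in v.items()}
            if k == "shared" and v else v)
        for k, v in sim.items()
    }
    clone_candidates = {f"clone{i + 1}": calls
                        for i, calls in enumerate(family.clones)}
    return genome, annotations, clone_candidates
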