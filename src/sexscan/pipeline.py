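"""End-to-end orchestration: simulate/load → filter → discover → classify →
scan → report.

The default design mirrors a two-stage study: sex-linked loci are discovered
by strict segregation in a named discovery subset, the discovered panel then
sexes the remaining (or all) individuals, and an exact-test genome scan over
the full cohort localizes the associated regions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import association_table, call_regions, scan, summarize
from .classify import classify_cohort, sex_call_table
from .core import GenotypeMatrix, SexscanError, read_sample_table, read_vcf
from .filters import PAPER_FILTERED_PRESET, apply_filters
from .segregation import SegregationCriterion, find_sex_linked, sex_linked_table
from .simulate import SimConfig, simulate, write_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one run.

    Exactly one of (``vcf`` + ``sample_table``) or ``sim`` provides the
    cohort.  ``discovery_samples`` names the subset used for segregation
    discovery (default: all samples); ``classify_samples`` is ``"rest"``
    (everyone not in the discovery subset), ``"all"``, or an explicit list —
    explicit discovery and classification lists must be disjoint.
    """

    outdir: Path
    vcf: Path | None = None
    sample_table: Path | None = None
    sim: SimConfig | None = None
    apply_site_filters: bool = False
    criterion: SegregationCriterion = field(default_factory=SegregationCriterion)
    discovery_samples: Sequence[str] | None = None
    classify_samples: str | Sequence[str] = "rest"
    sd_multiplier: float = 6.0
    merge_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        has_vcf = self.vcf is not None
        if has_vcf == (self.sim is not None):
            raise SexscanError("provide either a VCF + sample table or a SimConfig")
        if has_vcf and self.sample_table is None:
            raise SexscanError("a VCF input needs a sample table")


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix
    discovery: pd.DataFrame
    sex_calls: pd.DataFrame
    confusion: pd.DataFrame
    scan_results: list
    regions: pd.DataFrame
    total_sex_linked: int
    outdir: Path


def _resolve_subsets(config: PipelineConfig, all_ids: list[str]) -> tuple[list[str], list[str]]:
    discovery = list(config.discovery_samples) if config.discovery_samples else all_ids
    if isinstance(config.classify_samples, str):
        if config.classify_samples == "all":
            classify = all_ids
        elif config.classify_samples == "rest":
            discovery_set = set(discovery)
            classify = [i for i in all_ids if i not in discovery_set]
            if not classify:  # discovery used everyone
                classify = all_ids
        else:
            raise SexscanError(f"bad classify_samples {config.classify_samples!r}")
    else:
        classify = list(config.classify_samples)
        if config.discovery_samples is not None and set(classify) & set(discovery):
            raise SexscanError("explicit discovery and classification subsets overlap")
    return discovery, classify


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**params):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **params}

        return done

    # --- input ----------------------------------------------------------
    done = stage("input")
    if config.sim is not None:
        matrix, truth = simulate(config.sim)
        write_truth(truth, outdir / "truth")
        done(source="simulated", seed=config.sim.seed, n_loci=matrix.n_loci, n_samples=matrix.n_samples)
    else:
        matrix = read_vcf(config.vcf, read_sample_table(config.sample_table))
        done(source=str(config.vcf), n_loci=matrix.n_loci, n_samples=matrix.n_samples)

    # --- optional stringent site filtering ------------------------------
    if config.apply_site_filters:
        done = stage("site_filters")
        matrix, report = apply_filters(matrix, PAPER_FILTERED_PRESET)
        done(removed=report.removed, n_out=report.n_out)

    all_ids = [s.id for s in matrix.samples]
    discovery_ids, classify_ids = _resolve_subsets(config, all_ids)

    # --- discovery ------------------------------------------------------
    done = stage("discovery")
    discovery_matrix = matrix.subset_samples(discovery_ids)
    hits = find_sex_linked(discovery_matrix, config.criterion)
    discovery_df = sex_linked_table(hits)
    discovery_df.to_csv(outdir / "discovery.tsv", sep="\t", index=False)
    done(n_discovery_samples=len(discovery_ids), n_panel=len(hits),
         criterion=str(config.criterion))

    # map panel loci back to rows of the full matrix
    by_key = {(l.chrom, l.pos, l.ref, l.alt): i for i, l in enumerate(matrix.loci)}
    panel = [by_key[(h.locus.chrom, h.locus.pos, h.locus.ref, h.locus.alt)] for h in hits]

    # --- classification -------------------------------------------------
    done = stage("classification")
    if panel:
        calls, confusion = classify_cohort(matrix, panel, sample_ids=classify_ids)
        calls_df = sex_call_table(calls, matrix)
    else:
        logger.warning("empty panel: skipping classification")
        calls_df, confusion = pd.DataFrame(), pd.DataFrame()
    calls_df.to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)
    confusion.to_csv(outdir / "confusion.tsv", sep="\t")
    done(n_classified=len(calls_df))

    # --- genome scan ----------------------------------------------------
    done = stage("scan")
    results, skipped = scan(matrix)
    association_table(results).to_csv(outdir / "scan.tsv", sep="\t", index=False)
    regions = call_regions(results, config.sd_multiplier, config.merge_gap_bp) if len(results) >= 2 else []
    regions_df, total = summarize(regions)
    regions_df.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    done(n_tested=len(results), n_skipped=len(skipped), n_regions=len(regions_df),
         total_sex_linked=total)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return PipelineResult(
        matrix=matrix,
        discovery=discovery_df,
        sex_calls=calls_df,
        confusion=confusion,
        scan_results=results,
        regions=regions_df,
        total_sex_linked=total,
        outdir=outdir,
    )
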