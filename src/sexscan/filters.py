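"""Composable locus-level site filters.

Each filter is a pure predicate over the matrix it receives: the kept set is
the set of loci whose predicate holds, so filters commute when evaluated
against the same matrix.  Boundary semantics follow the usual hard-filtering
conventions: thresholds quoted as "higher than X" / "below X" / "more than
X%" are strict, so loci sitting exactly on a boundary are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, MISSING, minor_allele_freq, UndefinedFrequencyError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationThresholds:
    """Hard-filter cutoffs on variant-caller INFO annotations (all unitless)."""

    fs_max: float = 60.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    qd_min: float = 2.0
    mq_min: float = 40.0


@dataclass
class FilterReport:
    """Accounting of loci removed, per filter, in application order."""

    applied: list[str] = field(default_factory=list)
    removed: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def record(self, name: str, n_removed: int) -> None:
        self.applied.append(name)
        self.removed[name] = self.removed.get(name, 0) + n_removed

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(n_in=self.n_in or other.n_in, n_out=other.n_out)
        out.applied = self.applied + other.applied
        out.removed = dict(self.removed)
        for k, v in other.removed.items():
            out.removed[k] = out.removed.get(k, 0) + v
        return out

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def _apply(matrix: GenotypeMatrix, keep: np.ndarray, name: str) -> tuple[GenotypeMatrix, FilterReport]:
    report = FilterReport(n_in=matrix.n_loci, n_out=int(keep.sum()))
    report.record(name, int((~keep).sum()))
    return matrix.subset_loci(keep), report


def filter_annotations(
    matrix: GenotypeMatrix, thresholds: AnnotationThresholds = AnnotationThresholds()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci whose present INFO annotations violate any threshold.

    A locus lacking an annotation is never removed for that annotation;
    simulated VCFs carry no caller annotations and pass through untouched.
    """
    rules = (
        ("FS", lambda v: v > thresholds.fs_max),
        ("MQRankSum", lambda v: v < thresholds.mq_rank_sum_min),
        ("ReadPosRankSum", lambda v: v < thresholds.read_pos_rank_sum_min),
        ("QD", lambda v: v < thresholds.qd_min),
        ("MQ", lambda v: v < thresholds.mq_min),
    )
    keep = np.ones(matrix.n_loci, dtype=bool)
    n_unannotated = 0
    for i, locus in enumerate(matrix.loci):
        if not locus.info:
            n_unannotated += 1
            continue
        for key, violates in rules:
            value = locus.info.get(key)
            if value is not None and violates(value):
                keep[i] = False
                break
    if n_unannotated:
        logger.warning("%d loci carry no INFO annotations; kept unfiltered", n_unannotated)
    return _apply(matrix, keep, "annotations")


def filter_near_indel(matrix: GenotypeMatrix, window: int = 10) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove SNPs within ``window`` bp of an indel's REF footprint.

    Distance is measured from the SNP position to the indel's reference
    footprint [pos, pos+len(ref)-1]; a distance of exactly ``window`` still
    removes the SNP ("within").  Indels themselves are untouched here.
    """
    keep = np.ones(matrix.n_loci, dtype=bool)
    indels_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for locus in matrix.loci:
        if not locus.is_snp:
            indels_by_chrom.setdefault(locus.chrom, []).append(locus.ref_footprint)
    for i, locus in enumerate(matrix.loci):
        if not locus.is_snp:
            continue
        for start, stop in indels_by_chrom.get(locus.chrom, ()):
            distance = max(start - locus.pos, locus.pos - stop, 0)
            if distance <= window:
                keep[i] = False
                break
    return _apply(matrix, keep, "near_indel")


def filter_biallelic_snps(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep only biallelic SNPs (drop indels and multi-allelic sites)."""
    keep = np.array([l.is_snp and l.is_biallelic for l in matrix.loci], dtype=bool)
    return _apply(matrix, keep, "biallelic_snp")


def filter_mean_depth(matrix: GenotypeMatrix, max_mean: float = 30.0) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with mean read depth strictly above ``max_mean``.

    Loci without depth information are kept (with a warning): the filter is a
    no-op on matrices read from DP-less VCFs.
    """
    depths = [l.mean_depth for l in matrix.loci]
    n_unset = sum(d is None for d in depths)
    if n_unset:
        logger.warning("%d loci lack mean depth; depth filter skipped for them", n_unset)
    keep = np.array([d is None or d <= max_mean for d in depths], dtype=bool)
    return _apply(matrix, keep, "mean_depth")


def filter_maf(matrix: GenotypeMatrix, min_maf: float = 0.05) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci whose minor allele frequency is strictly below ``min_maf``.

    Frequency is pooled over all called samples; monomorphic and fully
    missing loci are removed.
    """
    keep = np.ones(matrix.n_loci, dtype=bool)
    calls = matrix.calls
    for i in range(matrix.n_loci):
        row = calls[i]
        triple = (
            int((row == 0).sum()),
            int((row == 1).sum()),
            int((row == 2).sum()),
        )
        try:
            keep[i] = minor_allele_freq(triple) >= min_maf
        except UndefinedFrequencyError:
            keep[i] = False
    return _apply(matrix, keep, "maf")


def filter_missing_per_population(
    matrix: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with more than ``max_missing`` missing data in any population."""
    populations = sorted({s.population for s in matrix.samples})
    keep = np.ones(matrix.n_loci, dtype=bool)
    for pop in populations:
        mask = np.array([s.population == pop for s in matrix.samples], dtype=bool)
        if not mask.any():
            continue
        frac = (matrix.calls[:, mask] == MISSING).mean(axis=1)
        keep &= frac <= max_missing
    return _apply(matrix, keep, "missing_per_population")


#: The stringent preset, in canonical order: caller-annotation hard filter,
#: indel-proximity filter, biallelic-SNP restriction, depth cap, MAF floor,
#: per-population missingness cap.
PAPER_FILTERED_PRESET = (
    filter_annotations,
    filter_near_indel,
    filter_biallelic_snps,
    filter_mean_depth,
    filter_maf,
    filter_missing_per_population,
)


def apply_filters(matrix: GenotypeMatrix, filters=PAPER_FILTERED_PRESET) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply a sequence of filters, chaining matrices and merging reports."""
    report = FilterReport(n_in=matrix.n_loci, n_out=matrix.n_loci)
    for fn in filters:
        matrix, step = fn(matrix)
        report = report.merge(step)
    report.n_in = report.n_in or matrix.n_loci
    report.n_out = matrix.n_loci
    return matrix, report
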