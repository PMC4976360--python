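"""Exact genotypic association with sex and SD-threshold region calling.

The per-locus test is Fisher-type: condition on both margins of the 2×3
sex-by-genotype table (column margins: per-sex called totals; row margins:
genotype totals) and sum the multivariate-hypergeometric point probabilities
of every table as or less probable than the observed one.  All accumulation
happens in log space (log-gamma point probabilities combined by stable
log-sum-exp), so p-values far below the smallest positive double — perfect
segregation in a ~226-fish cohort sits near 10⁻⁶⁷ and whole-genome scans
can go lower — remain exact in log form.

Region calling transforms p to −log₁₀ and clusters loci exceeding
mean + k·SD of the genome-wide transformed statistic into intervals bounded
by the first and last qualifying locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import (
    FEMALE,
    GenotypeCounts,
    GenotypeMatrix,
    Locus,
    MALE,
    SexCounts,
    minor_allele_freq,
)

LN10 = math.log(10.0)

#: Tables with point probability up to (1 + TIE_TOL) times the observed one
#: count as "as extreme"; absorbs floating-point ties between tables whose
#: exact probabilities are mathematically equal.
TIE_TOL = 1e-7

_LOG_TIE = math.log1p(TIE_TOL)


@dataclass(frozen=True)
class AssociationResult:
    locus: Locus
    counts: GenotypeCounts
    log_p: float  # natural log, <= 0

    @property
    def p(self) -> float:
        return math.exp(self.log_p)

    @property
    def neglog10_p(self) -> float:
        return -self.log_p / LN10


@dataclass(frozen=True)
class RegionSummary:
    """One sex-associated region: interval of above-threshold loci."""

    lg: str
    start: int
    stop: int
    n_sex_linked: int
    n_total: int
    max_neglog10_p: float

    @property
    def size(self) -> int:
        return self.stop - self.start


@lru_cache(maxsize=512)
def _margin_grid(c0: int, c1: int, c2: int, nf: int):
    """Log point probabilities of all 2×3 tables with the given margins.

    Margins: genotype totals (c0, c1, c2) and female called total nf (male
    total is implied).  Returns flat arrays (f0, f1, logprob) over all valid
    female rows; the male row is the margin complement.
    """
    n = c0 + c1 + c2
    nm = n - nf
    f0 = np.arange(max(0, c0 - nm), min(c0, nf) + 1)
    f1 = np.arange(0, min(c1, nf) + 1)
    g0, g1 = np.meshgrid(f0, f1, indexing="ij")
    g2 = nf - g0 - g1
    valid = (g2 >= 0) & (g2 <= c2) & (c1 - g1 <= nm)
    g0, g1, g2 = g0[valid], g1[valid], g2[valid]
    lgf = gammaln(np.arange(n + 2) + 1.0)  # lgf[k] = ln k! = ln Γ(k+1)

    def log_binom(nn, kk):
        return lgf[nn] - lgf[kk] - lgf[nn - kk]

    logp = (
        log_binom(c0, g0)
        + log_binom(c1, g1)
        + log_binom(c2, g2)
        - (lgf[n] - lgf[nf] - lgf[nm])
    )
    return g0, g1, logp


def fisher_exact_2x3(counts: GenotypeCounts) -> float:
    """Natural-log p of the exact genotypic (2×3) sex-association test.

    Missing individuals are excluded from the table.  Both sexes must have
    at least one called individual.
    """
    f = counts.females
    m = counts.males
    return log_p_from_table(f.as_triple(), m.as_triple())


def log_p_from_table(female_triple, male_triple) -> float:
    """Log p for explicit (hom_ref, het, hom_alt) rows, one per sex."""
    f0, f1, f2 = (int(x) for x in female_triple)
    m0, m1, m2 = (int(x) for x in male_triple)
    nf = f0 + f1 + f2
    nm = m0 + m1 + m2
    if nf == 0 or nm == 0:
        raise ValueError("both sexes need at least one called individual")
    c0, c1, c2 = f0 + m0, f1 + m1, f2 + m2
    g0, g1, logp = _margin_grid(c0, c1, c2, nf)
    obs = logp[(g0 == f0) & (g1 == f1)]
    if obs.size != 1:  # pragma: no cover - margins guarantee a unique cell
        raise AssertionError("observed table not found in margin grid")
    selected = logp[logp <= obs[0] + _LOG_TIE]
    peak = selected.max()  # stable log-sum-exp anchored at the largest term
    log_p = peak + math.log(np.exp(selected - peak).sum())
    return min(float(log_p), 0.0)


def scan(matrix: GenotypeMatrix, min_called_per_sex: int = 1) -> tuple[list[AssociationResult], list[Locus]]:
    """Exact genotypic test at every testable locus, genome order preserved.

    Returns (results, skipped) where ``skipped`` lists loci at which one sex
    had fewer than ``min_called_per_sex`` called individuals.
    """
    tables = {FEMALE: matrix.count_table(FEMALE), MALE: matrix.count_table(MALE)}
    results: list[AssociationResult] = []
    skipped: list[Locus] = []
    for i, locus in enumerate(matrix.loci):
        fc = SexCounts(*tables[FEMALE][i].tolist())
        mc = SexCounts(*tables[MALE][i].tolist())
        if fc.n_called < min_called_per_sex or mc.n_called < min_called_per_sex:
            skipped.append(locus)
            continue
        log_p = log_p_from_table(fc.as_triple(), mc.as_triple())
        results.append(AssociationResult(locus=locus, counts=GenotypeCounts(fc, mc), log_p=log_p))
    return results, skipped


def call_regions(
    results: list[AssociationResult],
    sd_multiplier: float = 6.0,
    merge_gap_bp: int = 1_000_000,
    maf_threshold: float = 0.05,
) -> list[RegionSummary]:
    """Cluster loci whose −log₁₀ p exceeds mean + ``sd_multiplier``·SD.

    The threshold statistics are computed over all tested loci (sample SD,
    n−1 denominator).  Qualifying loci on one chromosome are clustered
    greedily, splitting when consecutive qualifying loci lie more than
    ``merge_gap_bp`` apart.  ``n_total`` counts all tested loci inside the
    region interval with pooled MAF ≥ ``maf_threshold``.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 results for an SD threshold")
    stats = np.array([r.neglog10_p for r in results])
    threshold = stats.mean() + sd_multiplier * stats.std(ddof=1)

    above = [r for r in results if r.neglog10_p > threshold]
    clusters: list[list[AssociationResult]] = []
    for r in sorted(above, key=lambda r: (r.locus.chrom, r.locus.pos)):
        if (
            clusters
            and clusters[-1][-1].locus.chrom == r.locus.chrom
            and r.locus.pos - clusters[-1][-1].locus.pos <= merge_gap_bp
        ):
            clusters[-1].append(r)
        else:
            clusters.append([r])

    regions = []
    for cluster in clusters:
        chrom = cluster[0].locus.chrom
        start, stop = cluster[0].locus.pos, cluster[-1].locus.pos
        n_total = sum(
            1
            for r in results
            if r.locus.chrom == chrom
            and start <= r.locus.pos <= stop
            and r.counts.pooled_triple() != (0, 0, 0)
            and minor_allele_freq(r.counts.pooled_triple()) >= maf_threshold
        )
        regions.append(
            RegionSummary(
                lg=chrom,
                start=start,
                stop=stop,
                n_sex_linked=len(cluster),
                n_total=n_total,
                max_neglog10_p=max(r.neglog10_p for r in cluster),
            )
        )
    return regions


def summarize(regions: list[RegionSummary]) -> tuple[pd.DataFrame, int]:
    """Region report (LG, start, stop, size, counts, rounded max −log₁₀ p).

    Returns the per-region table and the grand total of sex-linked loci.
    The table rounds the max statistic to integer for display; callers
    wanting full precision use the :class:`RegionSummary` objects.
    """
    df = pd.DataFrame(
        {
            "lg": [r.lg for r in regions],
            "start": [r.start for r in regions],
            "stop": [r.stop for r in regions],
            "size": [r.size for r in regions],
            "n_sex_linked": [r.n_sex_linked for r in regions],
            "n_total": [r.n_total for r in regions],
            "max_neglog10_p": [int(round(r.max_neglog10_p)) for r in regions],
        }
    )
    total = int(df["n_sex_linked"].sum()) if len(df) else 0
    return df, total


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Per-locus scan output (chrom, pos, log_p, −log₁₀ p)."""
    return pd.DataFrame(
        {
            "chrom": [r.locus.chrom for r in results],
            "pos": [r.locus.pos for r in results],
            "log_p": [r.log_p for r in results],
            "neglog10_p": [r.neglog10_p for r in results],
        }
    )
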