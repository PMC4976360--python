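"""Synthetic diploid genotype cohorts with a planted sex haplotype.

The generator emulates the statistical structure a whole-genome sex scan
assumes: a wild cohort of ~110 males and ~116 females typed at 10⁴–10⁵
biallelic loci, Hardy-Weinberg background genotypes independent of sex, and
a small planted region where the heterogametic sex carries a dominant sex
haplotype (heterozygous carriers; the homogametic sex homozygous reference).
Observation noise mimics low-coverage short-read genotyping: heterozygote
dropout (a true het sampled as one homozygote), uniform genotype error and
missingness.  Loci are unlinked (no LD or recombination map) — the analyses
under test treat loci independently, so linkage structure is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    Locus,
    MALE,
    MISSING,
    SampleInfo,
)

XY = "XY"
ZW = "ZW"

#: Cohort-scale layout: 23 linkage groups (as in Atlantic cod), ~28 Mb each.
DEFAULT_CHROM_LENGTH = 28_000_000
DEFAULT_N_CHROMS = 23

#: Planted region defaults mirror the ~54 kb sex-associated interval on LG11.
DEFAULT_PLANTED = ("LG11", 11_864_114, 11_918_378, 200)


def default_layout(n_background_loci: int = 100_000, n_chroms: int = DEFAULT_N_CHROMS,
                   chrom_length: int = DEFAULT_CHROM_LENGTH) -> list[tuple[str, int, int]]:
    """Spread background loci evenly over ``n_chroms`` linkage groups."""
    base, extra = divmod(n_background_loci, n_chroms)
    return [
        (f"LG{i + 1:02d}", chrom_length, base + (1 if i < extra else 0))
        for i in range(n_chroms)
    ]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults reproduce the study-scale cohort."""

    n_males: int = 110
    n_females: int = 116
    chrom_layout: tuple = tuple(default_layout())
    planted: tuple = DEFAULT_PLANTED  # (chrom, start bp, stop bp, n_loci)
    system: str = XY
    linkage_completeness: float = 1.0  # P(carrier shows the het genotype)
    freq_low: float = 0.05  # background alt-frequency prior: Uniform(low, high)
    freq_high: float = 0.5
    genotype_error: float = 0.005
    het_dropout: float = 0.05
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in (XY, ZW):
            raise ValueError("system must be 'XY' or 'ZW'")
        for rate in (self.linkage_completeness, self.genotype_error, self.het_dropout, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        chrom, start, stop, n = self.planted
        lengths = {c: length for c, length, _ in self.chrom_layout}
        if n > 0:
            if chrom not in lengths:
                raise ValueError(f"planted chrom {chrom!r} not in layout")
            if not (1 <= start <= stop <= lengths[chrom]):
                raise ValueError("planted interval outside its chromosome")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: who is which sex and where the sex haplotype sits."""

    true_sex: dict[str, str]
    planted_chrom: str
    planted_positions: tuple[int, ...]
    linkage_completeness: float

    @property
    def planted_interval(self) -> tuple[int, int] | None:
        if not self.planted_positions:
            return None
        return min(self.planted_positions), max(self.planted_positions)


_BASES = np.array(list("ACGT"))


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a cohort under ``config``; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    heterogametic = MALE if config.system == XY else FEMALE

    samples = [
        SampleInfo(id=f"M{i + 1:04d}", phenotypic_sex=MALE, population="sim")
        for i in range(config.n_males)
    ] + [
        SampleInfo(id=f"F{i + 1:04d}", phenotypic_sex=FEMALE, population="sim")
        for i in range(config.n_females)
    ]
    n_samples = len(samples)
    carrier = np.array([s.phenotypic_sex == heterogametic for s in samples])

    # background loci: positions, alleles, HWE genotypes independent of sex
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom, length, n_loci in config.chrom_layout:
        pos = np.sort(rng.choice(length, size=n_loci, replace=False)) + 1
        chroms.extend([chrom] * n_loci)
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    n_background = pos_all.size

    freqs = rng.uniform(config.freq_low, config.freq_high, size=n_background)
    background = rng.binomial(2, freqs[:, None], size=(n_background, n_samples)).astype(np.int8)

    # planted loci: heterogametic carriers HET with prob λ, else HOM_REF
    p_chrom, p_start, p_stop, p_n = config.planted
    if p_n > 0:
        span = p_stop - p_start + 1
        p_pos = np.sort(rng.choice(span, size=min(p_n, span), replace=False)) + p_start
    else:
        p_pos = np.empty(0, dtype=int)
    planted = np.full((p_pos.size, n_samples), HOM_REF, dtype=np.int8)
    if p_pos.size:
        het_draw = rng.random((p_pos.size, n_samples)) < config.linkage_completeness
        planted[:, carrier] = np.where(het_draw[:, carrier], HET, HOM_REF)

    calls = np.concatenate([background, planted], axis=0) if (n_background or p_pos.size) else np.empty((0, n_samples), dtype=np.int8)
    chrom_all = np.array(chroms + [p_chrom] * p_pos.size)
    pos_full = np.concatenate([pos_all, p_pos]).astype(int)

    # noise, in fixed order: het dropout -> genotype error -> missingness
    if config.het_dropout > 0:
        het = calls == HET
        drop = het & (rng.random(calls.shape) < config.het_dropout)
        direction = rng.random(calls.shape) < 0.5
        calls[drop & direction] = HOM_REF
        calls[drop & ~direction] = HOM_ALT
    if config.genotype_error > 0:
        err = rng.random(calls.shape) < config.genotype_error
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)  # +1 or +2 mod 3
        calls[err] = (calls[err] + shift[err]) % 3
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    ref = rng.choice(4, size=pos_full.size)
    alt = (ref + rng.integers(1, 4, size=pos_full.size)) % 4
    loci = [
        Locus(chrom=str(chrom_all[i]), pos=int(pos_full[i]), ref=str(_BASES[ref[i]]), alt=str(_BASES[alt[i]]))
        for i in range(pos_full.size)
    ]

    matrix = GenotypeMatrix(loci, samples, calls).sorted_by_position()
    truth = SimTruth(
        true_sex={s.id: s.phenotypic_sex for s in samples},
        planted_chrom=p_chrom,
        planted_positions=tuple(int(p) for p in p_pos),
        linkage_completeness=config.linkage_completeness,
    )
    return matrix, truth


def write_truth(truth: SimTruth, outdir) -> tuple[Path, Path]:
    """Planted region as BED (0-based half-open) and true sexes as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = outdir / "planted_region.bed"
    with open(bed, "w") as fh:
        interval = truth.planted_interval
        if interval is not None:
            start, stop = interval
            fh.write(f"{truth.planted_chrom}\t{start - 1}\t{stop}\tplanted\n")
    tsv = outdir / "true_sex.tsv"
    pd.DataFrame(
        {"sample_id": list(truth.true_sex), "true_sex": list(truth.true_sex.values())}
    ).to_csv(tsv, sep="\t", index=False)
    return bed, tsv


def read_truth(outdir) -> tuple[tuple[str, int, int] | None, dict[str, str]]:
    """Inverse of :func:`write_truth` (interval back in 1-based inclusive)."""
    outdir = Path(outdir)
    interval = None
    bed = outdir / "planted_region.bed"
    if bed.stat().st_size > 0:
        chrom, start, stop = open(bed).read().split()[:3]
        interval = (chrom, int(start) + 1, int(stop))
    sexes = pd.read_csv(outdir / "true_sex.tsv", sep="\t")
    return interval, dict(zip(sexes.sample_id, sexes.true_sex))
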