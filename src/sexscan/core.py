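"""Genotype data model and VCF / sample-table input-output.

Genotypes are coded per (locus, sample) into a 4-state zygosity alphabet:
``HOM_REF``, ``HET``, ``HOM_ALT``, ``MISSING``.  Any heterozygous allele
combination (``0/1``, ``1/0``, ``0|1``, ``1/2`` ...) collapses to ``HET``
because every downstream statistic in this package depends on zygosity only.
Half-calls (``./1``) are treated as ``MISSING``.  Coordinates are 1-based
inclusive throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes (int8 in the calls matrix)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = 3

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT, MISSING)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_ALLELE_CHARS = set("ACGTN*")

#: INFO annotations carried through read/write when present on a record.
INFO_FIELDS = ("FS", "MQRankSum", "ReadPosRankSum", "QD", "MQ")


class SexscanError(Exception):
    """Base error for this package."""


class VcfParseError(SexscanError):
    """Malformed VCF content; message names the offending record."""


class ConfigError(SexscanError):
    """Inconsistent inputs (e.g. VCF samples not matching the metadata)."""


class UndefinedFrequencyError(SexscanError):
    """Allele frequency requested at a locus with zero called genotypes."""


@dataclass(frozen=True)
class Locus:
    """A variant site on a linkage group.

    ``alt`` is the primary alternative allele; additional alternatives of a
    multi-allelic record go to ``extra_alts`` and flip ``is_biallelic``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    extra_alts: tuple[str, ...] = ()
    mean_depth: float | None = None
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt, *self.extra_alts):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_biallelic(self) -> bool:
        return not self.extra_alts

    @property
    def ref_footprint(self) -> tuple[int, int]:
        """1-based inclusive interval covered by the REF allele."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class SampleInfo:
    id: str
    phenotypic_sex: str = UNKNOWN
    population: str = ""

    def __post_init__(self) -> None:
        if self.phenotypic_sex not in (MALE, FEMALE, UNKNOWN):
            raise ValueError(f"bad sex {self.phenotypic_sex!r} for sample {self.id}")


@dataclass(frozen=True)
class SexCounts:
    """Genotype counts within one sex at one locus."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_hom(self) -> int:
        return self.n_hom_ref + self.n_hom_alt

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing

    def as_triple(self) -> tuple[int, int, int]:
        return self.n_hom_ref, self.n_het, self.n_hom_alt


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-sex genotype counts at one locus (the 2×3 table plus missing)."""

    females: SexCounts
    males: SexCounts

    def pooled_triple(self) -> tuple[int, int, int]:
        f, m = self.females, self.males
        return (f.n_hom_ref + m.n_hom_ref, f.n_het + m.n_het, f.n_hom_alt + m.n_hom_alt)


class GenotypeMatrix:
    """Loci × samples matrix of coded genotypes with metadata.

    ``calls`` is an int8 array of shape (n_loci, n_samples) over the 4-state
    code alphabet.
    """

    def __init__(self, loci: Sequence[Locus], samples: Sequence[SampleInfo], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(loci), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(loci)}, {len(samples)})"
            )
        if calls.size and (calls.min() < HOM_REF or calls.max() > MISSING):
            raise ValueError("calls contain codes outside the 4-state domain")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.loci = list(loci)
        self.samples = list(samples)
        self.calls = calls

    # -- shape -----------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GenotypeMatrix {self.n_loci} loci x {self.n_samples} samples>"

    # -- subsetting ------------------------------------------------------
    def sex_mask(self, sex: str) -> np.ndarray:
        return np.array([s.phenotypic_sex == sex for s in self.samples], dtype=bool)

    def subset_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.loci[i] for i in index], self.samples, self.calls[index, :]
        )

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(ids)
        pos = {s.id: j for j, s in enumerate(self.samples)}
        missing = [i for i in wanted if i not in pos]
        if missing:
            raise ConfigError(f"samples not in matrix: {missing[:5]}")
        cols = [pos[i] for i in wanted]
        return GenotypeMatrix(self.loci, [self.samples[j] for j in cols], self.calls[:, cols])

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_loci), key=lambda i: (self.loci[i].chrom, self.loci[i].pos))
        return self.subset_loci(np.array(order, dtype=int))

    # -- counting --------------------------------------------------------
    def count_table(self, sex: str) -> np.ndarray:
        """(n_loci, 4) array of genotype-code counts among samples of ``sex``."""
        sub = self.calls[:, self.sex_mask(sex)]
        return np.stack([(sub == code).sum(axis=1) for code in GENOTYPE_CODES], axis=1)

    def missing_fraction(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        sub = self.calls if sample_mask is None else self.calls[:, sample_mask]
        if sub.shape[1] == 0:
            return np.zeros(self.n_loci)
        return (sub == MISSING).mean(axis=1)


def count_genotypes(matrix: GenotypeMatrix, locus_index: int, allow_unknown: bool = False) -> GenotypeCounts:
    """Per-sex genotype counts at one locus.

    Samples with unknown phenotypic sex raise :class:`ConfigError` unless
    ``allow_unknown`` explicitly excludes them from the table.
    """
    n_unknown = int(matrix.sex_mask(UNKNOWN).sum())
    if n_unknown and not allow_unknown:
        raise ConfigError(
            f"{n_unknown} samples have unknown sex; pass allow_unknown=True to exclude them"
        )
    row = matrix.calls[locus_index]
    out = {}
    for sex in (FEMALE, MALE):
        sub = row[matrix.sex_mask(sex)]
        out[sex] = SexCounts(
            n_hom_ref=int((sub == HOM_REF).sum()),
            n_het=int((sub == HET).sum()),
            n_hom_alt=int((sub == HOM_ALT).sum()),
            n_missing=int((sub == MISSING).sum()),
        )
    return GenotypeCounts(females=out[FEMALE], males=out[MALE])


def alt_allele_freq(counts) -> float:
    """Alternative-allele frequency from genotype counts.

    ``counts`` is a (n_hom_ref, n_het, n_hom_alt) triple, a :class:`SexCounts`
    or a :class:`GenotypeCounts` (pooled over sexes).
    """
    if isinstance(counts, GenotypeCounts):
        triple = counts.pooled_triple()
    elif isinstance(counts, SexCounts):
        triple = counts.as_triple()
    else:
        triple = tuple(counts)
    n_hom_ref, n_het, n_hom_alt = triple
    n_called = n_hom_ref + n_het + n_hom_alt
    if n_called < 1:
        raise UndefinedFrequencyError("no called genotypes; frequency undefined")
    return (n_het + 2 * n_hom_alt) / (2 * n_called)


def minor_allele_freq(counts) -> float:
    f = alt_allele_freq(counts)
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# sample metadata TSV  (columns: sample_id  sex  population)
# ---------------------------------------------------------------------------

def read_sample_table(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "sex"}
    if not required <= set(df.columns):
        raise ConfigError(f"sample table needs columns {sorted(required)}, got {list(df.columns)}")
    samples = [
        SampleInfo(
            id=row.sample_id,
            phenotypic_sex=row.sex if row.sex in (MALE, FEMALE) else UNKNOWN,
            population=getattr(row, "population", ""),
        )
        for row in df.itertuples()
    ]
    ids = [s.id for s in samples]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample ids in sample table")
    return samples


def write_sample_table(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.id for s in samples],
            "sex": [s.phenotypic_sex for s in samples],
            "population": [s.population for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input-output
# ---------------------------------------------------------------------------

def read_vcf(path, samples_meta: Sequence[SampleInfo] | str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT mandatory) into a :class:`GenotypeMatrix`.

    Phased and unphased genotypes are equivalent; half-calls and ``./.`` map
    to MISSING.  Multi-allelic records are retained and flagged (dropping
    them is the site filters' job).  FORMAT/DP, when present, is averaged
    over called samples into ``Locus.mean_depth``.
    """
    from cyvcf2 import VCF

    if isinstance(samples_meta, (str, Path)):
        samples_meta = read_sample_table(samples_meta)
    meta_by_id = {s.id: s for s in samples_meta}

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    vcf_ids = list(vcf.samples)
    unknown = [i for i in vcf_ids if i not in meta_by_id]
    if unknown:
        raise ConfigError(f"VCF samples missing from metadata: {unknown[:5]}")
    samples = [meta_by_id[i] for i in vcf_ids]

    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        try:
            alts = tuple(var.ALT) if var.ALT else ("N",)
            gts = var.genotypes  # [[a0, a1, phased], ...]
            row = np.empty(len(vcf_ids), dtype=np.int8)
            for j, gt in enumerate(gts):
                alleles = gt[:-1]
                if len(alleles) < 2 or any(a < 0 for a in alleles):
                    row[j] = MISSING
                elif alleles[0] == alleles[1]:
                    row[j] = HOM_REF if alleles[0] == 0 else HOM_ALT
                else:
                    row[j] = HET
            depth = None
            try:
                dp = var.format("DP")
            except Exception:
                dp = None
            if dp is not None:
                called = dp[row != MISSING]
                valid = called[called >= 0]
                if valid.size:
                    depth = float(np.mean(valid))
            info = {}
            for key in INFO_FIELDS:
                value = var.INFO.get(key)
                if value is not None:
                    info[key] = float(value)
            loci.append(
                Locus(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alts[0],
                    extra_alts=alts[1:],
                    mean_depth=depth,
                    info=info,
                )
            )
            rows.append(row)
        except SexscanError:
            raise
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record at {var.CHROM}:{var.POS}: {exc}"
            ) from exc

    calls = np.stack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(loci, samples, calls)


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as an uncompressed VCF v4.2 (GT only).

    Multi-allelic loci are written with all ALT alleles but their coded
    genotypes use allele 1; allele identity beyond zygosity is not stored in
    the matrix.
    """
    contigs: dict[str, int] = dict(contig_lengths or {})
    for locus in matrix.loci:
        end = locus.pos + len(locus.ref) - 1
        contigs[locus.chrom] = max(contigs.get(locus.chrom, 0), end)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key in INFO_FIELDS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.id for s in matrix.samples)
            + "\n"
        )
        for i, locus in enumerate(matrix.loci):
            alt = ",".join((locus.alt,) + locus.extra_alts)
            info = ";".join(f"{k}={v:g}" for k, v in locus.info.items()) or "."
            gts = "\t".join(_GT_STRINGS[c] for c in matrix.calls[i])
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )
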