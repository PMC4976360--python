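"""Sex-linked locus discovery via strict genotypic segregation.

Under an XX-XY system the heterogametic sex (males) is expected heterozygous
and the homogametic sex (females) homozygous at loci on the sex haplotype;
under ZZ-ZW the roles flip.  The discovery rule selects loci that are almost
exclusively heterozygous in one sex and homozygous in the other, with a
small discordance allowance absorbing genotyping error and heterozygote
dropout in low-coverage data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    GenotypeCounts,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MALE,
    MISSING,
    SexCounts,
    SexscanError,
)


@dataclass(frozen=True)
class SegregationCriterion:
    """Parametrized XX-XY / ZZ-ZW selection rule.

    A locus passes when the homogametic sex shows at most
    ``max_het_in_homogametic`` heterozygotes, the heterogametic sex at most
    ``max_hom_in_heterogametic`` homozygotes (hom-ref and hom-alt counted
    together), and the missing fraction stays within ``max_missing_frac``.
    Missingness is assessed over all samples jointly by default;
    ``per_sex_missing`` applies the cap within each sex instead.
    """

    heterogametic_sex: str = MALE
    max_het_in_homogametic: int = 2
    max_hom_in_heterogametic: int = 2
    max_missing_frac: float = 0.10
    per_sex_missing: bool = False

    def __post_init__(self) -> None:
        if self.heterogametic_sex not in (MALE, FEMALE):
            raise ValueError("heterogametic_sex must be 'male' or 'female'")
        if self.max_het_in_homogametic < 0 or self.max_hom_in_heterogametic < 0:
            raise ValueError("discordance allowances must be >= 0")
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")

    @property
    def homogametic_sex(self) -> str:
        return FEMALE if self.heterogametic_sex == MALE else MALE

    def flipped(self) -> "SegregationCriterion":
        return SegregationCriterion(
            heterogametic_sex=self.homogametic_sex,
            max_het_in_homogametic=self.max_het_in_homogametic,
            max_hom_in_heterogametic=self.max_hom_in_heterogametic,
            max_missing_frac=self.max_missing_frac,
            per_sex_missing=self.per_sex_missing,
        )


@dataclass(frozen=True)
class SexLinkedLocus:
    index: int  # row in the source matrix
    locus: "object"
    counts: GenotypeCounts


def find_sex_linked(matrix: GenotypeMatrix, criterion: SegregationCriterion = SegregationCriterion()) -> list[SexLinkedLocus]:
    """Loci segregating with sex under ``criterion``, sorted by (chrom, pos)."""
    female_mask = matrix.sex_mask(FEMALE)
    male_mask = matrix.sex_mask(MALE)
    if not female_mask.any() or not male_mask.any():
        raise SexscanError("both sexes must be represented in the cohort")

    tables = {FEMALE: matrix.count_table(FEMALE), MALE: matrix.count_table(MALE)}
    homog = tables[criterion.homogametic_sex]
    heterog = tables[criterion.heterogametic_sex]

    ok_homog = homog[:, HET] <= criterion.max_het_in_homogametic
    ok_heterog = (heterog[:, HOM_REF] + heterog[:, HOM_ALT]) <= criterion.max_hom_in_heterogametic
    if criterion.per_sex_missing:
        counted = female_mask | male_mask
        n_f, n_m = female_mask.sum(), male_mask.sum()
        ok_missing = (tables[FEMALE][:, MISSING] / n_f <= criterion.max_missing_frac) & (
            tables[MALE][:, MISSING] / n_m <= criterion.max_missing_frac
        )
    else:
        counted = female_mask | male_mask
        ok_missing = (
            (tables[FEMALE][:, MISSING] + tables[MALE][:, MISSING]) / counted.sum()
            <= criterion.max_missing_frac
        )

    passing = np.flatnonzero(ok_homog & ok_heterog & ok_missing)
    results = [
        SexLinkedLocus(
            index=int(i),
            locus=matrix.loci[i],
            counts=GenotypeCounts(
                females=SexCounts(*tables[FEMALE][i].tolist()),
                males=SexCounts(*tables[MALE][i].tolist()),
            ),
        )
        for i in passing
    ]
    results.sort(key=lambda r: (r.locus.chrom, r.locus.pos))
    return results


def orientation_sweep(matrix: GenotypeMatrix, criterion: SegregationCriterion = SegregationCriterion()) -> dict:
    """Run discovery under both heterogamety orientations with one threshold set.

    Returns ``{"XY": [...], "ZW": [...]}`` locus lists; the orientation whose
    list is non-empty (and whose mirror is empty) indicates the system.
    """
    xy = criterion if criterion.heterogametic_sex == MALE else criterion.flipped()
    zw = xy.flipped()
    return {"XY": find_sex_linked(matrix, xy), "ZW": find_sex_linked(matrix, zw)}


def sex_linked_table(results: list[SexLinkedLocus]) -> pd.DataFrame:
    """Discovery results as a table: locus, alleles, per-sex genotype counts."""
    return pd.DataFrame(
        {
            "chrom": [r.locus.chrom for r in results],
            "pos": [r.locus.pos for r in results],
            "ref": [r.locus.ref for r in results],
            "alt": [r.locus.alt for r in results],
            "female_hom_ref": [r.counts.females.n_hom_ref for r in results],
            "female_het": [r.counts.females.n_het for r in results],
            "female_hom_alt": [r.counts.females.n_hom_alt for r in results],
            "female_missing": [r.counts.females.n_missing for r in results],
            "male_hom_ref": [r.counts.males.n_hom_ref for r in results],
            "male_het": [r.counts.males.n_het for r in results],
            "male_hom_alt": [r.counts.males.n_hom_alt for r in results],
            "male_missing": [r.counts.males.n_missing for r in results],
        }
    )
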