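"""Bundled reference dataset: the Atlantic cod sex-locus summary tables.

Two small tables from the whole-genome characterization of the Atlantic cod
(*Gadus morhua*) sex locus serve as worked-example inputs and ground truth
for this package:

* per-sex genotype counts at the 13 sex-linked polymorphisms discovered on
  linkage group 11 in a 48-fish cohort (27 females, 21 males), and
* the six sex-associated regions found by the exact-test genome scan over
  55,160,622 variable sites in 110 males and 116 females.

Counts are (hom-ref, het, hom-alt) per sex; row sums below the cohort size
imply missing genotypes.
"""

from __future__ import annotations

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

N_DISCOVERY_FEMALES = 27
N_DISCOVERY_MALES = 21

#: chrom, pos, ref, alt, female (hom_ref, het, hom_alt), male (hom_ref, het, hom_alt)
DISCOVERY_PANEL_COUNTS: list[tuple] = [
    ("LG11", 11885753, "G", "T", (0, 2, 24), (1, 20, 0)),
    ("LG11", 11886873, "T", "A", (0, 0, 27), (1, 20, 0)),
    ("LG11", 11888434, "T", "C", (27, 0, 0), (0, 21, 0)),
    ("LG11", 11893118, "T", "A", (27, 0, 0), (1, 18, 1)),
    ("LG11", 11897471, "G", "GTGT", (0, 0, 27), (0, 21, 0)),
    ("LG11", 11897513, "C", "T", (0, 0, 27), (0, 20, 1)),
    ("LG11", 11897519, "A", "T", (0, 0, 27), (0, 21, 0)),
    ("LG11", 11897566, "AATCC", "A", (0, 1, 25), (1, 19, 0)),
    ("LG11", 11899188, "A", "G", (0, 0, 27), (0, 20, 1)),
    ("LG11", 11899196, "G", "T", (0, 0, 27), (0, 21, 0)),
    ("LG11", 11899391, "C", "CT", (0, 0, 27), (0, 21, 0)),
    ("LG11", 11899539, "G", "T", (0, 2, 25), (0, 20, 0)),
    ("LG11", 11899548, "TA", "T", (0, 2, 25), (0, 20, 0)),
]

#: lg, start, stop, n_sex_linked, n_total, max −log10 p — the six regions
#: called at the 6-SD threshold in the 226-fish scan.
REGION_TABLE: list[tuple] = [
    ("LG08a", 1_784_400, 1_784_813, 11, 23, 47),
    ("LG08b", 24_118_524, 24_118_864, 8, 14, 19),
    ("LG11", 11_864_114, 11_918_378, 127, 472, 67),
    ("LG14", 27_062_221, 27_062_388, 3, 8, 22),
    ("LG15", 3_678_047, 3_679_605, 14, 64, 41),
    ("LG17", 18_769_676, 18_769_822, 3, 6, 26),
]

#: cohort-level totals from the same study
N_VARIANTS_UNFILTERED = 55_160_622
N_SNPS_FILTERED = 1_573_340
N_SCAN_FEMALES = 116
N_SCAN_MALES = 110


def _fill_column(triple: tuple[int, int, int], n_samples: int) -> list[int]:
    """Expand per-sex counts into individual genotype codes (missing pads)."""
    hom_ref, het, hom_alt = triple
    codes = [HOM_REF] * hom_ref + [HET] * het + [HOM_ALT] * hom_alt
    codes += [MISSING] * (n_samples - len(codes))
    return codes


def discovery_cohort() -> GenotypeMatrix:
    """The 48-fish discovery cohort reconstructed from the printed counts.

    Individual identities are synthetic (counts do not identify fish), but
    every per-locus per-sex genotype count matches the published table, so
    all count-based statistics are exact.
    """
    samples = [
        SampleInfo(id=f"F{i + 1:02d}", phenotypic_sex=FEMALE, population="Lofoten")
        for i in range(N_DISCOVERY_FEMALES)
    ] + [
        SampleInfo(id=f"M{i + 1:02d}", phenotypic_sex=MALE, population="Lofoten")
        for i in range(N_DISCOVERY_MALES)
    ]
    loci = []
    rows = []
    for chrom, pos, ref, alt, female, male in DISCOVERY_PANEL_COUNTS:
        loci.append(Locus(chrom=chrom, pos=pos, ref=ref, alt=alt))
        rows.append(
            _fill_column(female, N_DISCOVERY_FEMALES) + _fill_column(male, N_DISCOVERY_MALES)
        )
    return GenotypeMatrix(loci, samples, np.array(rows, dtype=np.int8))


def region_table() -> pd.DataFrame:
    """The six published regions in the scan report's column order."""
    return pd.DataFrame(
        REGION_TABLE,
        columns=["lg", "start", "stop", "n_sex_linked", "n_total", "max_neglog10_p"],
    )
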