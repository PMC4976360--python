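"""Genetic sexing from per-individual heterozygosity over a sex-linked panel.

For each individual, the method-of-moments inbreeding coefficient

    F = (O_hom - E_hom) / (L - E_hom)

compares the observed number of homozygous panel sites O_hom with the number
E_hom expected under Hardy-Weinberg, over the L panel sites called in that
individual.  At a site with cohort alternative-allele frequency p estimated
from n called diploids, the expected homozygous probability includes the
small-sample correction on heterozygosity:

    E_site = 1 - 2 p (1 - p) * 2n / (2n - 1)

Over a panel of XX-XY sex-linked loci, females (homozygous) push F toward
+1 and males (heterozygous) toward strongly negative values, so the sign of
F calls genetic sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MALE,
    MISSING,
    SexscanError,
    UNKNOWN,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexCall:
    """Genetic sex call for one individual with the F components behind it."""

    sample_id: str
    o_hom: int
    e_hom: float
    l_sites: int
    f: float | None
    call: str  # female | male | unknown

    @staticmethod
    def from_components(sample_id: str, o_hom: int, e_hom: float, l_sites: int) -> "SexCall":
        if l_sites == 0:
            return SexCall(sample_id, 0, 0.0, 0, None, UNKNOWN)
        denom = l_sites - e_hom
        if denom == 0:
            return SexCall(sample_id, o_hom, e_hom, l_sites, None, UNKNOWN)
        f = (o_hom - e_hom) / denom
        call = FEMALE if f > 0 else MALE if f < 0 else UNKNOWN
        return SexCall(sample_id, o_hom, e_hom, l_sites, f, call)


def _panel_expectations(
    matrix: GenotypeMatrix, panel: Sequence[int], small_sample_correction: bool = True
) -> tuple[list[int], np.ndarray]:
    """Usable panel rows and their per-site expected homozygous probability.

    Sites where the cohort allele frequency is 0 or 1 (or fewer than two
    individuals are called) carry no information about heterozygosity excess
    and are excluded with a warning.
    """
    usable: list[int] = []
    e_site: list[float] = []
    for i in panel:
        row = matrix.calls[i]
        called = row != MISSING
        n = int(called.sum())
        if n < 2:
            logger.warning("panel locus %d: <2 called individuals; excluded", i)
            continue
        n_alt = int((row[called] == HET).sum() + 2 * (row[called] == HOM_ALT).sum())
        p = n_alt / (2 * n)
        if p in (0.0, 1.0):
            logger.warning("panel locus %d: monomorphic in cohort; excluded", i)
            continue
        correction = (2 * n) / (2 * n - 1) if small_sample_correction else 1.0
        e_site.append(1.0 - 2.0 * p * (1.0 - p) * correction)
        usable.append(i)
    return usable, np.asarray(e_site)


def inbreeding_f(
    matrix: GenotypeMatrix,
    panel: Sequence[int],
    sample_id: str,
    small_sample_correction: bool = True,
) -> SexCall:
    """F and the sex call for one sample over ``panel`` (locus row indices)."""
    usable, e_site = _panel_expectations(matrix, panel, small_sample_correction)
    ids = [s.id for s in matrix.samples]
    try:
        j = ids.index(sample_id)
    except ValueError:
        raise SexscanError(f"sample {sample_id!r} not in matrix") from None
    calls = matrix.calls[usable, j] if usable else np.empty(0, dtype=np.int8)
    called = calls != MISSING
    o_hom = int(((calls == HOM_REF) | (calls == HOM_ALT)).sum())
    e_hom = float(e_site[called].sum())
    return SexCall.from_components(sample_id, o_hom, e_hom, int(called.sum()))


def classify_cohort(
    matrix: GenotypeMatrix,
    panel: Sequence[int],
    sample_ids: Sequence[str] | None = None,
    small_sample_correction: bool = True,
) -> tuple[list[SexCall], pd.DataFrame]:
    """Sex-call every sample and tabulate genetic vs phenotypic sex.

    Returns the per-sample calls and a confusion table (rows: phenotypic sex,
    columns: genetic call) restricted to samples with a known phenotype.
    Allele frequencies always come from the full cohort in ``matrix``; the
    optional ``sample_ids`` restricts only who gets classified.
    """
    if not panel:
        raise SexscanError("panel is empty")
    usable, e_site = _panel_expectations(matrix, panel, small_sample_correction)
    ids = [s.id for s in matrix.samples]
    wanted = list(sample_ids) if sample_ids is not None else ids
    index = {s: j for j, s in enumerate(ids)}
    calls_out: list[SexCall] = []
    for sid in wanted:
        if sid not in index:
            raise SexscanError(f"sample {sid!r} not in matrix")
        col = matrix.calls[usable, index[sid]] if usable else np.empty(0, dtype=np.int8)
        called = col != MISSING
        o_hom = int(((col == HOM_REF) | (col == HOM_ALT)).sum())
        calls_out.append(
            SexCall.from_components(sid, o_hom, float(e_site[called].sum()), int(called.sum()))
        )

    pheno = {s.id: s.phenotypic_sex for s in matrix.samples}
    rows = []
    for call in calls_out:
        rows.append((pheno.get(call.sample_id, UNKNOWN), call.call))
    labelled = [(p, g) for p, g in rows if p in (FEMALE, MALE)]
    confusion = (
        pd.crosstab(
            pd.Series([p for p, _ in labelled], name="phenotypic"),
            pd.Series([g for _, g in labelled], name="genetic"),
        )
        if labelled
        else pd.DataFrame()
    )
    return calls_out, confusion


def sex_call_table(calls: Sequence[SexCall], matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Per-sample report: F components, call, phenotype and concordance."""
    pheno = {s.id: s.phenotypic_sex for s in matrix.samples} if matrix is not None else {}
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "o_hom": [c.o_hom for c in calls],
            "e_hom": [c.e_hom for c in calls],
            "l_sites": [c.l_sites for c in calls],
            "f": [c.f for c in calls],
            "call": [c.call for c in calls],
        }
    )
    if pheno:
        df["phenotypic_sex"] = [pheno.get(c.sample_id, UNKNOWN) for c in calls]
        df["concordant"] = [
            c.call == pheno.get(c.sample_id) if pheno.get(c.sample_id) in (FEMALE, MALE) else pd.NA
            for c in calls
        ]
    return df
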