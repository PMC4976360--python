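import math

import numpy as np
import pytest

from _oracles import fisher_2x3_exact
from sexscan.core import (
    FEMALE,
    GenotypeCounts,
    GenotypeMatrix,
    Locus,
    MALE,
    SampleInfo,
    SexCounts,
)
from sexscan.association import (
    AssociationResult,
    RegionSummary,
    association_table,
    call_regions,
    fisher_exact_2x3,
    log_p_from_table,
    scan,
    summarize,
)
from sexscan.reference_data import REGION_TABLE
from sexscan.simulate import SimConfig, default_layout, simulate

LN10 = math.log(10)


def _result(chrom, pos, neglog10, maf=0.3, n=100):
    """AssociationResult with a prescribed statistic and pooled MAF."""
    n_alt = int(round(2 * n * maf))
    counts = GenotypeCounts(
        females=SexCounts(n - n_alt, n_alt, 0, 0), males=SexCounts(n, 0, 0, 0)
    )
    return AssociationResult(
        locus=Locus(chrom, pos, "A", "G"), counts=counts, log_p=-neglog10 * LN10
    )


class TestFisherExact2x3:
    @pytest.mark.parametrize(
        "female, male",
        [
            ((5, 3, 2), (4, 4, 2)),
            ((10, 0, 0), (0, 10, 0)),
            ((1, 1, 1), (9, 9, 9)),
            ((0, 7, 0), (6, 0, 6)),
            ((12, 2, 1), (3, 8, 4)),
        ],
    )
    def test_sampled_tables_match_rational_oracle(self, female, male):
        exact = fisher_2x3_exact(female, male)
        log_p = log_p_from_table(female, male)
        assert log_p == pytest.approx(math.log(exact), rel=1e-12, abs=1e-12)

    def test_single_genotype_row_gives_p_one(self):
        # only one nonzero genotype column: a 2×1 table has a single outcome
        assert log_p_from_table((8, 0, 0), (5, 0, 0)) == 0.0

    def test_monomorphic_locus_p_one(self):
        counts = GenotypeCounts(SexCounts(10, 0, 0, 0), SexCounts(12, 0, 0, 0))
        assert fisher_exact_2x3(counts) == 0.0

    @pytest.mark.parametrize("nf, nm", [(7, 5), (27, 21), (116, 110)])
    def test_perfect_segregation_closed_form(self, nf, nm):
        """All-hom females vs all-het males: the observed table is the unique
        most-extreme one, so p = 1 / C(nf+nm, nf)."""
        log_p = log_p_from_table((nf, 0, 0), (0, nm, 0))
        expected = -(math.lgamma(nf + nm + 1) - math.lgamma(nf + 1) - math.lgamma(nm + 1))
        assert log_p == pytest.approx(expected, rel=1e-12)

    def test_extreme_tail_exact_in_log_form(self):
        log_p = log_p_from_table((116, 0, 0), (0, 110, 0))
        assert 0.0 < math.exp(log_p) < 1e-66
        assert -log_p / LN10 == pytest.approx(66.72, abs=0.01)

    def test_empty_sex_rejected(self):
        with pytest.raises(ValueError):
            log_p_from_table((0, 0, 0), (3, 3, 3))

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            f = tuple(int(x) for x in rng.integers(0, 8, 3))
            m = tuple(int(x) for x in rng.integers(0, 8, 3))
            if sum(f) == 0 or sum(m) == 0:
                continue
            assert log_p_from_table(f, m) <= 0.0


class TestScan:
    def test_discovery_cohort_gives_13_strong_results(self, cod_discovery):
        results, skipped = scan(cod_discovery)
        assert len(results) == 13 and not skipped
        assert all(r.neglog10_p >= 10 for r in results)

    def test_genome_order_preserved(self, random_matrix):
        m = random_matrix(n_loci=40, n_samples=16, seed=17)
        results, _ = scan(m)
        assert [r.locus.pos for r in results] == [l.pos for l in m.loci]

    def test_per_locus_p_unaffected_by_other_loci(self, random_matrix):
        m = random_matrix(n_loci=30, n_samples=16, seed=19)
        full, _ = scan(m)
        sub, _ = scan(m.subset_loci(np.arange(10)))
        assert [r.log_p for r in sub] == [r.log_p for r in full[:10]]

    def test_one_sex_all_missing_skipped(self):
        samples = [SampleInfo(id="f1", phenotypic_sex=FEMALE),
                   SampleInfo(id="f2", phenotypic_sex=FEMALE),
                   SampleInfo(id="m1", phenotypic_sex=MALE)]
        calls = np.array([[0, 1, 3]], dtype=np.int8)
        m = GenotypeMatrix([Locus("LG01", 5, "A", "G")], samples, calls)
        results, skipped = scan(m)
        assert not results and len(skipped) == 1

    def test_null_type_one_error_is_conservative(self):
        """On a sex-free cohort the exact test rejects at most nominally."""
        cfg = SimConfig(
            chrom_layout=tuple(default_layout(10_000, n_chroms=4)),
            planted=("LG01", 1, 1, 0), seed=23,
        )
        m, _ = simulate(cfg)
        results, _ = scan(m)
        frac = np.mean([r.p < 0.05 for r in results])
        assert frac <= 0.05

    def test_permuted_labels_give_super_uniform_p(self, cod_discovery):
        """Exact-test p-values under label permutation are stochastically
        at least uniform (conservative)."""
        rng = np.random.default_rng(37)
        sexes = [s.phenotypic_sex for s in cod_discovery.samples]
        ps = []
        for _ in range(100):
            perm = rng.permutation(len(sexes))
            samples = [
                SampleInfo(id=s.id, phenotypic_sex=sexes[perm[j]], population=s.population)
                for j, s in enumerate(cod_discovery.samples)
            ]
            shuffled = GenotypeMatrix(cod_discovery.loci, samples, cod_discovery.calls)
            results, _ = scan(shuffled)
            ps.extend(r.p for r in results)
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            # 4 SD binomial slack on the empirical fraction
            slack = 4 * math.sqrt(alpha * (1 - alpha) / ps.size)
            assert (ps <= alpha).mean() <= alpha + slack


class TestCallRegions:
    def test_single_planted_cluster_recovered_exactly(self):
        rng = np.random.default_rng(41)
        background = [
            _result("LG01", int(p), float(x))
            for p, x in zip(np.sort(rng.choice(10**7, 3000, replace=False)) + 1,
                            rng.exponential(0.4, 3000))
        ]
        cluster_pos = sorted(int(p) for p in rng.choice(50_000, 20, replace=False) + 5_000_000)
        cluster = [_result("LG02", p, 40.0 + rng.random()) for p in cluster_pos]
        regions = call_regions(background + cluster)
        assert len(regions) == 1
        assert (regions[0].lg, regions[0].start, regions[0].stop) == (
            "LG02", cluster_pos[0], cluster_pos[-1]
        )
        assert regions[0].n_sex_linked == len(cluster)

    def test_distant_extremes_split_into_two_regions(self):
        # two extreme loci 22 Mb apart on one chromosome
        results = [_result("LG08", 2_000_000, 50.0), _result("LG08", 24_000_000, 50.0)]
        results += [_result("LG08", p, 0.2) for p in range(3_000_000, 20_000_000, 100_000)]
        regions = call_regions(results, merge_gap_bp=1_000_000)
        assert len(regions) == 2
        assert all(r.n_sex_linked == 1 for r in regions)

    def test_constant_statistic_yields_no_regions(self):
        results = [_result("LG01", p, 1.0) for p in range(1000, 5000, 100)]
        assert call_regions(results) == []

    def test_region_accounting(self):
        rng = np.random.default_rng(43)
        results = [
            _result(f"LG{c:02d}", int(p), float(x))
            for c, p, x in zip(rng.integers(1, 5, 800),
                               rng.integers(1, 10**7, 800),
                               rng.exponential(0.4, 800))
        ]
        results += [_result("LG09", 100 + i, 30.0) for i in range(5)]
        results.sort(key=lambda r: (r.locus.chrom, r.locus.pos))
        regions = call_regions(results)
        stats = np.array([r.neglog10_p for r in results])
        threshold = stats.mean() + 6 * stats.std(ddof=1)
        n_above = int((stats > threshold).sum())
        assert sum(r.n_sex_linked for r in regions) == n_above

    def test_n_total_applies_maf_floor(self):
        cluster = [_result("LG01", p, 30.0, maf=0.3) for p in (100, 200, 300)]
        low_maf_inside = _result("LG01", 150, 0.1, maf=0.01)
        background = [_result("LG02", p, 0.3) for p in range(1000, 200_000, 200)]
        regions = call_regions(cluster + [low_maf_inside] + background)
        assert len(regions) == 1
        assert regions[0].n_sex_linked == 3
        assert regions[0].n_total == 3  # the low-MAF locus inside is not counted


class TestSummarize:
    def test_published_region_table_totals(self):
        regions = [
            RegionSummary(lg=lg, start=start, stop=stop, n_sex_linked=n_sl,
                          n_total=n_tot, max_neglog10_p=float(max_p))
            for lg, start, stop, n_sl, n_tot, max_p in REGION_TABLE
        ]
        df, total = summarize(regions)
        assert total == 166
        assert df.set_index("lg").loc["LG11", "size"] == 54264
        assert df.set_index("lg").loc["LG08a", "size"] == 413
        assert list(df.columns) == [
            "lg", "start", "stop", "size", "n_sex_linked", "n_total", "max_neglog10_p"
        ]

    def test_single_region_total(self):
        region = RegionSummary("LG01", 10, 20, n_sex_linked=4, n_total=6, max_neglog10_p=12.3)
        df, total = summarize([region])
        assert total == 4
        assert df["max_neglog10_p"].iloc[0] == 12

    def test_empty(self):
        df, total = summarize([])
        assert total == 0 and len(df) == 0


def test_association_table_columns(cod_discovery):
    results, _ = scan(cod_discovery)
    df = association_table(results)
    assert list(df.columns) == ["chrom", "pos", "log_p", "neglog10_p"]
    assert (df.neglog10_p > 0).all()
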