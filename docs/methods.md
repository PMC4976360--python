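# Methods

## Genotype model

All statistics operate on zygosity alone, so genotypes are coded per
(locus, sample) into four states: hom-ref, het, hom-alt, missing. Any
heterozygous allele combination (including `1/2` at multi-allelic sites)
collapses to het; half-calls (`./1`) and `./.` are missing. Phasing is
ignored. Coordinates are 1-based inclusive (VCF convention); only the BED
writer converts to 0-based half-open. Multi-allelic records are read and
flagged rather than dropped, leaving their removal to the site filters so
that stage responsibilities stay separate. Since the matrix stores
zygosity, allele identity beyond "primary alternative" is not preserved on
write; round-trips are exact for biallelic data.

## Site filters

The stringent "filtered dataset" preset chains six per-locus predicates:
caller-annotation hard filter (FS > 60, MQRankSum < −12.5,
ReadPosRankSum < −8, QD < 2, MQ < 40 — a locus missing an annotation is
never removed for it, so simulated annotation-free VCFs pass through);
removal of SNPs within 10 bp of an indel's REF footprint
[pos, pos+len(ref)−1]; restriction to biallelic SNPs; mean FORMAT/DP cap
of 30; MAF floor of 0.05 pooled over all called samples; and a 10%
missingness cap applied per population. All quoted thresholds are read
strictly ("higher than 30" removes 30.5 but keeps 30.0; "below 0.05"
removes 0.049 but keeps 0.05; "more than 10%" keeps exactly 10%). The
indel-proximity rule uses the full REF footprint, not just POS: this is
well defined for multi-base deletions and errs conservative. Each filter
is a pure predicate of the matrix it receives, so content-based filters
commute; the indel-proximity predicate depends on indels still being
present, which is why the preset runs it before the biallelic restriction.
The depth cap is computed over all samples jointly (a per-population
variant would change little and is not offered).

## Segregation discovery

A locus passes the XX-XY criterion when (a) heterozygotes among females ≤
`max_het_in_homogametic`, (b) homozygotes among males ≤
`max_hom_in_heterogametic`, (c) missing fraction ≤ `max_missing_frac`;
the ZZ-ZW criterion swaps the sex roles. Defaults are 2 / 2 / 0.10. Both
homozygote classes count toward (b): a male column of 1/18/1 (hom-ref /
het / hom-alt) has two discordant homozygotes and passes at the default
allowance. The tolerance of two exists to absorb heterozygote dropout in
low-coverage data; it is exposed as a free parameter rather than hardwired.
Missingness is assessed over all sexed samples jointly by default (the
natural reading of a single "10% missing" allowance); a per-sex mode is
available via `per_sex_missing`. Indels are eligible alongside SNPs, so
discovery is normally run on the unfiltered matrix — real sex-linked panels
contain indel polymorphisms that the stringent preset would discard.

## Inbreeding-coefficient sexing

For individual *i* over panel sites where *i* is called:
F = (O_hom − E_hom)/(L − E_hom), with per-site expected homozygosity
1 − 2p̂(1−p̂)·2n/(2n−1); p̂ is the alt-allele frequency over all called
diploids at the site and n their count. The 2n/(2n−1) small-sample factor
matches the standard method-of-moments heterozygosity estimator used by
common VCF toolkits; an uncorrected mode exists for sensitivity checks.
Frequencies deliberately come from the full cohort (both sexes): at
application time the classifier has no other frequency source, and at a
true XX-XY site the pooled frequency sits near 0.25–0.5, which is exactly
what drives females toward F ≈ +1 and males strongly negative. Sites
monomorphic in the cohort (p̂ ∈ {0,1}) or with fewer than two called
individuals carry no information and are excluded with a warning. F = 0 or
an empty called panel yields "unknown" rather than a forced call. F is
invariant under ref↔alt relabeling and is fully deterministic.

## Exact genotypic association scan

Per locus, missing individuals are excluded and the 2×3 sex-by-genotype
table tested by conditioning on both margins: the p-value is the sum of
multivariate-hypergeometric point probabilities over all same-margin
tables whose point probability is at most (1 + 10⁻⁷) times the observed
one. The tie tolerance mirrors common exact-test implementations and
absorbs floating-point ties between tables whose exact probabilities are
mathematically equal. Point probabilities are computed from a log-factorial
(log-gamma) table and accumulated by log-sum-exp anchored at the largest
selected term, so results are exact in log form arbitrarily deep into the
tail — a perfectly segregating locus in a 226-individual cohort has
−log₁₀ p ≈ 66.7, and the implementation agrees with an exact rational
enumeration to ~10⁻¹⁴ relative error over every margin configuration with
n ≤ 30. Enumerated grids are memoized by margin configuration (bounded
LRU), which makes repeated tests at shared margins cheap.

Region calling computes the threshold mean + k·SD (default k = 6, sample
SD with n−1; at realistic locus counts the ddof choice is irrelevant but
it is fixed for reproducibility) over **all** tested loci genome-wide,
then clusters strictly-above-threshold loci per chromosome, splitting
where consecutive qualifying loci are more than `merge_gap_bp` = 1 Mb
apart — wide enough to hold a ~55 kb cluster together, narrow enough to
split regions ~22 Mb apart on one linkage group. A region reports
start/stop at its first/last qualifying locus, size = stop − start,
the count of qualifying ("sex-linked") loci, the count of all tested loci
in [start, stop] with pooled MAF ≥ 0.05, and its maximum −log₁₀ p (rounded
to integer in the report table, full precision retained in the objects).
A degenerate scan with constant statistic has SD = 0 and calls nothing.

### Calibration of the SD threshold

The k·SD rule is adaptive, and that cuts both ways. When a real (planted)
signal is present it inflates the genome-wide SD so the threshold rises
far above the null tail: in study-scale simulations (10⁵ background loci,
200 planted loci, 226 individuals) the threshold lands near −log₁₀ p ≈ 16
and the scan calls exactly the planted region with no false positives.
On a **pure-null** cohort, however, −log₁₀ p of a well-calibrated test is
approximately exponential (mean and SD ≈ 1/ln 10 ≈ 0.43), so mean + 6·SD
sits near 3.0 and about 10⁻³·L loci exceed it by chance — roughly ten
singleton "regions" per 10⁴ null loci. Zero-region outcomes on null data
are therefore not expected at k = 6 with 10⁴ well-powered loci; the rule
is a signal-contrast heuristic, not a family-wise error control. Users
wanting null robustness should raise k, require a minimum cluster size, or
permute labels to set an empirical threshold.

## Synthetic cohorts

Defaults emulate a wild whole-genome-sequenced cod cohort: 110 males and
116 females, 10⁵ background loci spread over 23 linkage groups of 28 Mb,
and 200 sex-linked loci planted in LG11:11,864,114–11,918,378 (the ~54 kb
scale of the real locus). Background loci draw alt frequency from
Uniform(0.05, 0.5) and genotypes i.i.d. Hardy–Weinberg independent of sex
— no linkage disequilibrium, recombination map or population structure,
because the analyses under test treat loci independently; passing tests
therefore say nothing about LD-induced clustering of false positives in
real data. Planted loci make homogametic individuals hom-ref and
heterogametic carriers het with probability λ (`linkage_completeness`,
default 1; λ < 1 emulates inconsistently sex-linked flanking regions).
Noise is applied in a fixed, documented order — het dropout δ (true het
observed as either homozygote, equally split; default 0.05, the effective
stand-in for coverage-driven het loss at ~10× depth), then uniform
genotype error ε (default 0.005), then missingness m (default 0.05) —
order matters only at second order in the rates. A single `default_rng`
seeded once drives all draws, so equal seeds give bit-identical cohorts.

## End-pair utility

Long reads become artificial paired-end reads by slicing `end_len`
(default 300 bp) off each end; mate 2 is reverse-complemented to standard
FR orientation (toggleable, since some aligner workflows expect forward
strand), FASTQ qualities are sliced in register and reversed with the
sequence. Reads shorter than 2·end_len are skipped and counted rather than
emitted as overlapping mates, which would misrepresent insert size.

## Pipeline

`run_pipeline` mirrors the two-stage study design: discovery on a named
subset (e.g. one population sample of 27 females and 21 males), F-based
classification of the remaining — or optionally all — individuals against
the discovered panel, and the exact-test scan plus region calling over the
full cohort. Explicitly requested discovery and classification subsets
must be disjoint. All stage outputs are TSV plus a JSON run log (package
version, stage parameters, wall times); outputs are pure functions of
(inputs, parameters, seed), and reruns are byte-identical.

## Problem sizes used in the test suite

The bundled checks run at desk scale by design: the oracle comparison
enumerates all 2×3 tables with n ≤ 30; the parameter-recovery check uses
the default 10⁵-background-locus cohort; null calibration uses 10 seeds of
10⁴ loci; unit tests use cohorts of tens of samples and 10²–10⁴ loci.
Genome-scale inputs (tens of millions of variants) are supported by the
same code paths — the scan is linear in loci with bounded per-locus
enumeration — but are not exercised in the suite.
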