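import numpy as np
import pytest

from sexscan.core import FEMALE, MALE, GenotypeMatrix, Locus, SampleInfo
from sexscan.reference_data import discovery_cohort


@pytest.fixture(scope="session")
def cod_discovery():
    """The 48-fish discovery cohort rebuilt from the published counts."""
    return discovery_cohort()


@pytest.fixture
def random_matrix():
    """Factory for random biallelic matrices with both sexes present."""

    def make(n_loci=50, n_samples=20, seed=0, missing_rate=0.05, chrom="LG01"):
        rng = np.random.default_rng(seed)
        samples = [
            SampleInfo(
                id=f"S{j:03d}",
                phenotypic_sex=MALE if j % 2 else FEMALE,
                population="popA" if j < n_samples // 2 else "popB",
            )
            for j in range(n_samples)
        ]
        pos = np.sort(rng.choice(10**6, size=n_loci, replace=False)) + 1
        loci = [Locus(chrom=chrom, pos=int(p), ref="A", alt="G") for p in pos]
        freqs = rng.uniform(0.1, 0.9, size=n_loci)
        calls = rng.binomial(2, freqs[:, None], size=(n_loci, n_samples)).astype(np.int8)
        calls[rng.random(calls.shape) < missing_rate] = 3
        return GenotypeMatrix(loci, samples, calls)

    return make
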