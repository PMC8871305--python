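import numpy as np
import pandas as pd
import pytest

from oaprs.genotype import GenotypeMatrix, SnpRecord, MISSING


def make_matrix(dosages, snp_ids=None, chroms=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain nested list / array of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snp_ids = snp_ids or [f"rs{j}" for j in range(m)]
    chroms = chroms or ["1"] * m
    snps = [SnpRecord(id=s, chrom=c, pos=j + 1, minor_allele="A",
                      major_allele="G")
            for j, (s, c) in enumerate(zip(snp_ids, chroms))]
    return GenotypeMatrix(dosages, snps, [f"S{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort():
    """Balanced 100-sample cohort with a numeric covariate."""
    r = np.random.default_rng(7)
    n = 100
    return pd.DataFrame({
        "sample": [f"S{i}" for i in range(n)],
        "case": np.r_[np.ones(50, int), np.zeros(50, int)],
        "age": r.uniform(40, 75, n),
        "sex": r.integers(0, 2, n),
    })
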