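import numpy as np
import pytest

from wgpred import (
    GenotypeMatrix,
    SNPRecord,
    SimConfig,
    compute_grm,
    mean_impute_genotypes,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 200-subject cohort with a heritable trait (h2=0.5)."""
    return simulate_cohort(SimConfig(n_subjects=200, n_snps=600, seed=11))


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    return compute_grm(mean_impute_genotypes(small_cohort.genotypes))


def make_genotypes(dosages, chroms=None, subject_prefix="S"):
    """Build a GenotypeMatrix from a plain dosage array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = chroms or ["1"] * m
    snps = [SNPRecord(f"rs{i}", str(chroms[i]), 100 + i) for i in range(m)]
    return GenotypeMatrix([f"{subject_prefix}{i}" for i in range(n)], snps, dosages)
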