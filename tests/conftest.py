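import numpy as np
import pytest

from bmimr import SimulationConfig, generate_cohort
from bmimr.simulate import GenotypeMatrix


@pytest.fixture(scope="session")
def cohort50k():
    """One default-calibration 50,000-individual cohort, shared across tests."""
    cohort, genotypes, weights = generate_cohort(SimulationConfig(n_individuals=50_000, seed=1))
    return cohort, genotypes, weights


@pytest.fixture(scope="session")
def cohort5k():
    """A small cohort for cheap structural tests."""
    cohort, genotypes, weights = generate_cohort(SimulationConfig(n_individuals=5_000, seed=7))
    return cohort, genotypes, weights


def make_genotypes(dosage, ids=None, alleles=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim == 1:
        dosage = dosage[:, None]
    n_var = dosage.shape[1]
    if ids is None:
        ids = [f"rsT{j}" for j in range(n_var)]
    return GenotypeMatrix(dosage, ids, alleles)
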