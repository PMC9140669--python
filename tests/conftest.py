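import numpy as np
import pytest

from sfmoabc import GenotypeDataset, SimulationSpec, builtin_models, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def perfect_ds():
    """12 SNPs, 40 samples; SNPs 3 and 7 jointly determine the phenotype
    (case iff both carry at least one minor allele)."""
    g = np.random.default_rng(7).integers(0, 3, size=(40, 12))
    y = ((g[:, 3] > 0) & (g[:, 7] > 0)).astype(int)
    return GenotypeDataset(genotypes=g, phenotype=y, truth=[(3, 7)])


@pytest.fixture(scope="session")
def model4_ds():
    """One moderately sized Model 4 dataset shared across tests."""
    spec = SimulationSpec(
        model=builtin_models()["Model 4"],
        n_cases=500,
        n_controls=500,
        n_snps=30,
        seed=42,
    )
    return simulate_dataset(spec)
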