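import numpy as np
import pytest

from pedbench import GenotypeMatrix, SimulationConfig, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Small migration + random-mating simulation shared across tests."""
    cfg = SimulationConfig(n_founders=30, n_generations=4, n_snps=400,
                           n_chromosomes=4, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def clustered_genotypes():
    """Three drifted subpopulations, 60 individuals x 240 sites, plus labels.

    Subpopulation allele frequencies are independent Beta-perturbed draws
    around a shared ancestral frequency, giving visible cluster structure.
    """
    rng = np.random.default_rng(42)
    n_per, n_sites = 20, 240
    anc = rng.uniform(0.2, 0.8, size=n_sites)
    blocks, labels = [], []
    for k in range(3):
        p = np.clip(anc + rng.normal(0, 0.18, size=n_sites), 0.02, 0.98)
        blocks.append(rng.binomial(2, p, size=(n_per, n_sites)))
        labels.extend([k] * n_per)
    values = np.concatenate(blocks).astype(np.uint8)
    X = GenotypeMatrix(values=values, ids=[f"ind{i}" for i in range(3 * n_per)])
    return X, np.asarray(labels)
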