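import numpy as np
import pytest

import phylocomm as pc


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config simulated experiment (seed 42) shared across tests."""
    cfg = pc.SimulationConfig(rng_seed=42)
    tree, table, truth = pc.simulate_dataset(cfg)
    return cfg, tree, table, truth


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    _, _, table, _ = default_dataset
    presence = pc.call_presence(pc.positive_fraction(table), 0.9)
    return pc.build_abundance_matrix(table, presence)


def make_matrix(abundance, present=None, taxa=None, samples=None):
    """Small TaxonAbundanceMatrix helper for hand-built examples."""
    abundance = np.asarray(abundance, dtype=float)
    if present is None:
        present = np.ones_like(abundance, dtype=bool)
    n_t, n_s = abundance.shape
    taxa = taxa or [f"t{i}" for i in range(n_t)]
    samples = samples or [f"s{j}" for j in range(n_s)]
    return pc.TaxonAbundanceMatrix(taxa, samples, abundance, np.asarray(present, bool))
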