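import numpy as np
import pytest

from divscan.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete synthetic study reused across read-only tests."""
    cfg = SimConfig(
        seed=7,
        genome_length=120_000,
        n_scaffolds=2,
        n_genes=20,
        gene_length=2_000,
        min_gene_gap=300,
        n_motifs=3,
        planted_gene_fraction=0.2,
        sweep_gene_fraction=0.1,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
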