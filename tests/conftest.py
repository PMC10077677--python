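import numpy as np
import pytest

from irekit.simulate import SimConfig, simulate_genome_pair


@pytest.fixture(scope="session")
def small_truth():
    """A small paired-genome simulation shared across tests (~2 s)."""
    cfg = SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=400_000,
        n_genes=40,
        n_enhancers=60,
        tss_distance=(4_000, 30_000),
    )
    return simulate_genome_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
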