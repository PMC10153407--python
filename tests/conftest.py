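import numpy as np
import pytest

from mc3net.synthetic import (
    GenomeConfig,
    TruthConfig,
    simulate_contact_cells,
    simulate_genome,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(
        GenomeConfig(chromosomes=(("chr1", 8_000_000),), n_genes=40, n_tfs=8), seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_genome):
    cfg = TruthConfig(
        n_subset_loops=6,
        n_shared_boundaries=6,
        n_differential_boundaries=5,
        n_boundary_couplings=2,
        n_master_tfs=1,
        master_targets=3,
        n_triple_tfs=4,
        targets_per_tf=1,
        n_decoy_dmrs=12,
    )
    methylome, truth = simulate_methylomes(small_genome, cfg, n_subclasses=6, seed=12)
    return methylome, truth


@pytest.fixture(scope="session")
def small_cells(small_genome, small_truth):
    _, truth = small_truth
    return simulate_contact_cells(small_genome, truth, 6, 40_000, seed=13)


@pytest.fixture(scope="session")
def small_features(small_genome, small_cells):
    from mc3net import workflow

    return workflow.collect_contact_features(small_genome, small_cells, "chr1")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
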