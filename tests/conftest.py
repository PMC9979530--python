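import pytest

from ebsseq import ReferenceGenome, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """Moderate synthetic dataset with default (realistic) chemistry."""
    config = SimulationConfig(
        seed=7,
        genome_length=40_000,
        n_genes=5,
        gene_length=3_000,
        n_islands=3,
        island_length=600,
        library_size=1_500,
        spike_copies=300,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def sim_noiseless():
    """Limit chemistry: perfect deamination, 5hmC never converts, no noise."""
    config = SimulationConfig(
        seed=11,
        genome_length=40_000,
        n_genes=5,
        gene_length=3_000,
        n_islands=3,
        island_length=600,
        library_size=1_500,
        p_convert={"C": 1.0, "5mC": 1.0, "5hmC": 0.0, "5fC": 0.0},
        error_rate=0.0,
        capture_prob=1.0,
        carryover_prob=0.0,
        duplicate_rate=0.0,
    )
    return simulate_dataset(config, with_spikes=False)


@pytest.fixture()
def tiny_genome():
    return ReferenceGenome({"c1": "ACGTACGGTCAGNCGA", "c2": "CGCG"})
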