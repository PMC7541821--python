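import numpy as np
import pytest

from virlink.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A small community: two high-ingestion lineages, one low."""
    return SimulationConfig(
        seed=42,
        n_sags_per_lineage={"Choanozoa": 4, "Picozoa": 4, "Alveolata": 5},
        lineage_grazing_rate={"Choanozoa": 6.0, "Picozoa": 3.0, "Alveolata": 0.3},
        bacterial_prey_prob={"Choanozoa": 0.4, "Picozoa": 0.2, "Alveolata": 0.1},
        n_virus_genomes=12,
        n_bacterial_genomes=4,
        n_euk_genomes=6,
        dsdna_genome_length_range=(8000, 20000),
        bact_genome_length_range=(20000, 30000),
    )


@pytest.fixture(scope="session")
def noiseless_config(small_config):
    import dataclasses
    return dataclasses.replace(small_config, evidence_fp=0.0, evidence_fn=0.0)
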