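import numpy as np
import pytest

from denovoscenario import (
    PipelineConfig,
    SimConfig,
    SpeciesTree,
    run_pipeline,
    simulate_catalogue,
)

#: species tree with short branches (all <= 0.1 substitutions/site) used
#: for recovery-style tests
RECOVERY_TREE = "((cerevisiae:0.05,paradoxus:0.05)A1:0.03,mikatae:0.10)A2;"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated data set shared across tests."""
    config = SimConfig(
        tree_spec=RECOVERY_TREE,
        n_loci_per_class={"S0+": 6, "S1": 6, "S2": 6, "intergene": 25},
        locus_length=150,
        flank_length=80,
        seed=7,
    )
    return config, simulate_catalogue(config)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Full pipeline run on the shared small simulation."""
    _, sim = small_sim
    tree = SpeciesTree(RECOVERY_TREE)
    config = PipelineConfig(flank_length=80, min_orf_length=60)
    return config, sim, run_pipeline(sim.genomes, sim.catalogue, tree, config)
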