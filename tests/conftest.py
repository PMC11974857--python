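import numpy as np
import pytest

from rhodoflag.synthetic_data import (
    SimConfig,
    evolve_proteomes,
    plant_fgcs,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated genome set shared by read-only tests.

    6 taxa, 12 background families, one fla2 transfer and one fla3
    placement; fla1 with occasional loss.
    """
    seed = 11
    tree = simulate_species_tree(6, seed)
    genomes = evolve_proteomes(tree, 12, 100, 0.15, seed)
    config = SimConfig(
        n_taxa=6, n_families=12, n_hgt_fla2=1, n_hgt_fla3=1, loss_prob_fla1=0.1
    )
    genomes, truth = plant_fgcs(genomes, tree, config, seed)
    return {"tree": tree, "genomes": genomes, "truth": truth, "config": config, "seed": seed}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
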