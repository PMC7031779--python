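import numpy as np
import pytest

import revenant as r


@pytest.fixture(scope="session")
def small_run():
    """A modest full simulation shared by read-only tests.

    Birth-death tree with at least one extinct lineage and three survivors,
    genomes evolved under all six event types.
    """
    tree = r.simulate_complete_tree(1.0, 0.5, stop_time=3.0, seed=0)
    assert tree.extinct() and len(tree.alive_at_end()) >= 2
    root_genome = r.init_root_genome(5, seed=1, lineage_id=tree.root_id)
    rates = r.RateConfig(
        duplication=0.05, loss=0.05, inversion=0.05, transposition=0.05,
        transfer=0.05, origination=0.1,
        duplication_extension=1.5, loss_extension=1.5, transfer_extension=1.5,
    )
    result = r.evolve_genomes(tree, root_genome, rates, "G", seed=42)
    return tree, root_genome, rates, result


@pytest.fixture(scope="session")
def small_gene_trees(small_run):
    tree, root_genome, _, result = small_run
    return r.build_all_gene_trees(result, root_genome, tree)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
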