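import pytest

from phyclus import GeneratorConfig, clustering_system, fixtures, gen_random_level1


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def random_level1_nets():
    """A reusable pool of small random level-1 networks (varied block counts
    and shapes, all phylogenetic/separated/tree-child by construction)."""
    nets = []
    for seed in range(60):
        for n, blocks in ((5, 1), (7, 2), (6, 0)):
            nets.append(
                gen_random_level1(
                    GeneratorConfig(n_leaves=n, n_blocks=blocks, seed=seed)
                )
            )
    return nets


@pytest.fixture(scope="session")
def random_level1_systems(random_level1_nets):
    return [clustering_system(n) for n in random_level1_nets]
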