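import networkx as nx
import pytest

from phagenet import SimConfig, generate_community, profile_from_proteomes


@pytest.fixture(scope="session")
def planted_community():
    """3 clusters x 10 genomes, 20 core / 10 accessory @0.5 / 3 background."""
    config = SimConfig(
        n_clusters=3,
        genomes_per_cluster=10,
        core_families_per_cluster=20,
        accessory_families_per_cluster=10,
        accessory_carry_prob=0.5,
        background_families_per_genome=3,
        seed=1,
    )
    proteomes, truth = generate_community(config)
    return proteomes, truth


@pytest.fixture(scope="session")
def planted_profile(planted_community):
    proteomes, _ = planted_community
    return profile_from_proteomes(proteomes)


@pytest.fixture
def bridged_cliques():
    """Two 3-cliques joined by a single bridge edge, unit weights."""
    graph = nx.Graph()
    for clique in (("a1", "a2", "a3"), ("b1", "b2", "b3")):
        for i in range(3):
            for j in range(i + 1, 3):
                graph.add_edge(clique[i], clique[j], weight=1.0)
    graph.add_edge("a1", "b1", weight=1.0)
    return graph
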