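import networkx as nx
import pytest

from mirspan import SyntheticConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down scenario for fast end-to-end tests: 4 blocks of 12 genes
    in a 300-gene universe, 30 seeds, 12 families of 12 targets."""
    return SyntheticConfig(
        rng_seed=7, n_blocks=4, block_size=12, p_within=0.5, p_between=0.02,
        n_background=252, p_background=0.004, n_seeds=30, n_families=12,
        targets_per_family=12, chip_n_per_group=5, qpcr_n_per_group=8,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return simulate_scenario(small_config)


@pytest.fixture(scope="session")
def small_scenario_dir(small_scenario, tmp_path_factory):
    from mirspan import write_scenario

    outdir = tmp_path_factory.mktemp("scenario")
    paths = write_scenario(small_scenario, outdir)
    return paths


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single edge; ground-truth modules are the
    cliques."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


@pytest.fixture
def two_triangles():
    """Two triangles joined by one bridge edge (Q of the triangle partition
    is 5/14)."""
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C"),
                     ("D", "E"), ("E", "F"), ("D", "F"), ("C", "D")])
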