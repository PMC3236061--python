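import numpy as np
import pytest

from joda.pathway import PathwayTopology, build_model
from joda.synthetic import SyntheticConfig, four_gene_fixture, generate

HUB_REGULATORS = ("ATM", "RelA", "p53")
HUB_EDGES_DAMAGED = (("ATM", "RelA"), ("ATM", "p53"))


@pytest.fixture(scope="session")
def topo_healthy():
    return PathwayTopology("h", HUB_REGULATORS, ())


@pytest.fixture(scope="session")
def topo_damaged():
    return PathwayTopology("d", HUB_REGULATORS, HUB_EDGES_DAMAGED)


@pytest.fixture(scope="session")
def model_healthy(topo_healthy):
    return build_model(topo_healthy)


@pytest.fixture(scope="session")
def model_damaged(topo_damaged):
    return build_model(topo_damaged)


@pytest.fixture(scope="session")
def four_gene():
    return four_gene_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted dataset shared by pipeline-level tests."""
    return generate(SyntheticConfig(n_genes=200, targets_per_regulator=20,
                                    seed=5))


def random_topology(rng: np.random.Generator, n_nodes: int,
                    density: float, population: str = "t") -> PathwayTopology:
    """Random directed graph over <= 12 nodes; cycles allowed."""
    nodes = tuple(f"v{i}" for i in range(n_nodes))
    edges = tuple(
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and rng.random() < density
    )
    return PathwayTopology(population, nodes, edges)


def reachability_oracle(topology: PathwayTopology) -> dict:
    """Independent per-pair reachability by iterative depth-first search."""
    adj = {v: [] for v in topology.regulators}
    for u, v in topology.edges:
        adj[u].append(v)
    reach = {}
    for start in topology.regulators:
        seen = {start}  # empty path: every node reaches itself
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        reach[start] = seen
    return reach
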