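import random

import networkx as nx
import pytest

from netmod import synthetic


@pytest.fixture(scope="session")
def default_truth(tmp_path_factory):
    """The standard synthetic corpus generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = synthetic.default_spec(seed=11)
    truth = synthetic.generate(spec, outdir)
    return spec, truth


@pytest.fixture()
def two_cliques():
    """Two 10-node cliques joined by a single bridge edge."""
    g = nx.Graph()
    for offset, prefix in ((0, "A"), (0, "B")):
        members = [f"{prefix}{i}" for i in range(10)]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                g.add_edge(u, v, score=900)
    g.add_edge("A0", "B0", score=900)
    return g


def random_scored_graph(n, p, seed):
    rng = random.Random(seed)
    g = nx.Graph()
    nodes = [f"N{i:03d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if rng.random() < p:
                g.add_edge(u, v, score=rng.randint(150, 1000))
    return g
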