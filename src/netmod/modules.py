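"""Size-bounded topological module detection and the module-level graph.

Topological modules are communities of the interactome with denser internal
than external connectivity, found by modularity maximisation (Louvain).
Because very large communities are useless for enrichment analysis, any
community above ``max_size`` is recursively re-partitioned on its induced
subgraph until every module is within bounds or a community refuses to
split.  Communities below ``min_size`` are kept but flagged small so that
downstream stages can exclude them.

The module graph summarises inter-module connectivity: for two modules
with ``a`` and ``b`` members joined by ``c`` interactome edges, the edge
weight is ``c / (a * b)`` — the density of realised cross-connections,
which equals 1 exactly for a complete bipartite connection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.community import louvain_communities

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 400


@dataclass(frozen=True)
class Module:
    module_id: str
    members: frozenset[str]
    small: bool = False
    unsplittable: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ModulePartition:
    """Disjoint modules covering every node of the source graph."""

    modules: tuple[Module, ...]
    source_graph_nodes: int

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.modules)
        if total != self.source_graph_nodes:
            raise ValueError(
                f"modules cover {total} nodes, source graph has {self.source_graph_nodes}"
            )
        seen: set[str] = set()
        for m in self.modules:
            if m.members & seen:
                raise ValueError(f"module {m.module_id} overlaps another module")
            seen |= m.members

    def membership(self) -> dict[str, str]:
        """node -> module_id lookup."""
        return {node: m.module_id for m in self.modules for node in m.members}

    def by_id(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def analyzed(self, min_size: int = DEFAULT_MIN_SIZE) -> tuple[Module, ...]:
        """Modules at or above the minimum size (the enrichment-eligible set)."""
        return tuple(m for m in self.modules if m.size >= min_size)


def _sorted_subgraph(g: nx.Graph, nodes=None) -> nx.Graph:
    # Rebuild with sorted node/edge insertion so community detection sees a
    # canonical adjacency order regardless of how the caller built the graph.
    h = nx.Graph()
    members = sorted(g.nodes if nodes is None else nodes)
    h.add_nodes_from(members)
    member_set = set(members)
    for a, b, data in sorted(g.edges(data=True)):
        if a in member_set and b in member_set:
            h.add_edge(a, b, **data)
    return h


def detect_modules(
    g: nx.Graph,
    max_size: int = DEFAULT_MAX_SIZE,
    min_size: int = DEFAULT_MIN_SIZE,
    seed: int = 0,
    weighted: bool = False,
) -> ModulePartition:
    """Louvain community detection with recursive splitting of large modules.

    Parameters
    ----------
    g
        The interactome (confidence scores in the ``score`` edge attribute).
    max_size, min_size
        Size bounds on modules.  Oversized communities are re-partitioned on
        their induced subgraph; undersized ones are retained but flagged.
    seed
        Seed for the Louvain tie-breaking randomness; the partition is
        deterministic for a fixed seed and input.
    weighted
        When True, modularity uses the confidence scores as edge weights;
        the default treats the (already score-filtered) graph as binary.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect modules on an empty graph")
    if not max_size > min_size >= 1:
        raise ValueError(f"need max_size > min_size >= 1, got {max_size}, {min_size}")
    weight = "score" if weighted else None

    final: list[tuple[frozenset[str], bool]] = []  # (members, unsplittable)

    def split(subg: nx.Graph, depth: int) -> None:
        comms = louvain_communities(subg, weight=weight, seed=seed)
        if len(comms) <= 1:
            unsplittable = subg.number_of_nodes() > max_size
            if unsplittable:
                logger.info(
                    "community of %d nodes is unsplittable at depth %d",
                    subg.number_of_nodes(), depth,
                )
            final.append((frozenset(subg.nodes), unsplittable))
            return
        for comm in sorted(comms, key=min):
            if len(comm) > max_size:
                split(_sorted_subgraph(subg, comm), depth + 1)
            else:
                final.append((frozenset(comm), False))

    split(_sorted_subgraph(g), 0)

    final.sort(key=lambda item: min(item[0]))
    modules = tuple(
        Module(
            module_id=f"M{i + 1}",
            members=members,
            small=len(members) < min_size,
            unsplittable=unsplittable,
        )
        for i, (members, unsplittable) in enumerate(final)
    )
    n_small = sum(m.small for m in modules)
    logger.info(
        "detected %d modules (%d flagged small) over %d nodes",
        len(modules), n_small, g.number_of_nodes(),
    )
    return ModulePartition(modules=modules, source_graph_nodes=g.number_of_nodes())


@dataclass(frozen=True)
class ModuleGraphEdge:
    module_a: str
    module_b: str
    c: int       # realised cross edges
    weight: float  # c / (a * b)


@dataclass(frozen=True)
class ModuleGraph:
    nodes: tuple[str, ...]
    edges: tuple[ModuleGraphEdge, ...]

    def degree(self, module_id: str) -> int:
        return sum(1 for e in self.edges if module_id in (e.module_a, e.module_b))


def module_graph(g: nx.Graph, p: ModulePartition) -> ModuleGraph:
    """Weighted module-level graph with edge weight c / (a * b).

    ``c`` is the number of interactome edges running between the two
    modules and ``a``, ``b`` are their member counts; an edge is emitted
    only when ``c >= 1``.
    """
    member_of = p.membership()
    sizes = {m.module_id: m.size for m in p.modules}
    cross: dict[tuple[str, str], int] = {}
    for u, v in g.edges():
        mu, mv = member_of[u], member_of[v]
        if mu == mv:
            continue
        key = (mu, mv) if mu < mv else (mv, mu)
        cross[key] = cross.get(key, 0) + 1
    edges = tuple(
        ModuleGraphEdge(a, b, c, c / (sizes[a] * sizes[b]))
        for (a, b), c in sorted(cross.items())
    )
    return ModuleGraph(nodes=tuple(m.module_id for m in p.modules), edges=edges)


def top_degree_modules(mg: ModuleGraph, k: int) -> list[tuple[str, int]]:
    """Top-k modules by module-graph degree, ties broken by module_id."""
    if not mg.nodes:
        raise ValueError("empty module graph")
    ranked = sorted(
        ((mid, mg.degree(mid)) for mid in mg.nodes),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[: min(k, len(ranked))]


def write_membership(p: ModulePartition, path, header: str | None = None) -> None:
    """Two-column TSV: protein, module_id (sorted by protein)."""
    member_of = p.membership()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("protein\tmodule_id\n")
        for node in sorted(member_of):
            fh.write(f"{node}\t{member_of[node]}\n")


def write_module_graph(mg: ModuleGraph, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_a\tmodule_b\tc\tweight\n")
        for e in mg.edges:
            fh.write(f"{e.module_a}\t{e.module_b}\t{e.c}\t{e.weight:.6g}\n")
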