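"""Synthetic pipeline inputs with known ground truth.

Real disease-module studies rest on statistical structure that public
databases provide but that cannot be redistributed or re-derived at desk
scale: an assortative interactome (dense communities, sparse between),
disease genes concentrated in a few communities, annotation terms enriched
in those communities, and drug targets sitting close to the disease genes.
This module generates all pipeline input files with that structure planted
explicitly, so every downstream stage can be tested against ground truth.

The interactome is a planted-partition (stochastic block model) graph:
node pairs within a block are joined with probability ``p_within``,
between blocks with ``p_between``.  Confidence scores emulate a
high-confidence subset: within-block edges score >= 700 with probability
0.9, between-block edges with probability 0.3, so filtering at 700 keeps
the community structure while thinning the noise.

Everything is driven by one integer seed; regenerating with the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

# defaults mirror the planted-partition conditions used throughout the
# test suite: strongly assortative blocks of ~100 nodes
DEFAULT_P_WITHIN = 0.3
DEFAULT_P_BETWEEN = 0.01


@dataclass(frozen=True)
class ScoreLaw:
    """Rule assigning confidence scores to within/between-block edges."""

    p_high_within: float = 0.9
    p_high_between: float = 0.3
    high_range: tuple[int, int] = (700, 1000)
    low_range: tuple[int, int] = (400, 699)

    def draw(self, rng: random.Random, within: bool) -> int:
        p_high = self.p_high_within if within else self.p_high_between
        lo, hi = self.high_range if rng.random() < p_high else self.low_range
        return rng.randint(lo, hi)


@dataclass(frozen=True)
class DiseaseSpec:
    disease_id: str
    home_blocks: tuple[int, ...]
    n_genes: int
    leak_rate: float = 0.0  # fraction of genes placed outside the home blocks


@dataclass(frozen=True)
class TermSpec:
    term_id: str
    namespace: str  # BP / CC / MF / pathway
    home_block: int | None  # None -> decoy term drawn uniformly
    size: int


@dataclass(frozen=True)
class DrugSpec:
    drug_id: str
    indication_class: str  # e.g. "AED" or "other"
    n_targets: int
    max_hop_to_seed: int | None  # None -> targets drawn uniformly


@dataclass(frozen=True)
class SyntheticSpec:
    n_blocks: int = 5
    block_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    p_within: float = DEFAULT_P_WITHIN
    p_between: float = DEFAULT_P_BETWEEN
    score_law: ScoreLaw = field(default_factory=ScoreLaw)
    diseases: tuple[DiseaseSpec, ...] = ()
    terms: tuple[TermSpec, ...] = ()
    drugs: tuple[DrugSpec, ...] = ()
    unexpressed_genes: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        if not all(s >= 1 for s in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must be in [0, 1]")
        for d in self.diseases:
            if not 0.0 <= d.leak_rate <= 1.0:
                raise ValueError(f"{d.disease_id}: leak_rate outside [0, 1]")
            capacity = sum(self.block_sizes[b] for b in d.home_blocks)
            if d.leak_rate == 0.0 and d.n_genes > capacity:
                raise ValueError(
                    f"{d.disease_id}: {d.n_genes} genes cannot fit in home blocks "
                    f"of total size {capacity} with zero leak"
                )


@dataclass(frozen=True)
class GroundTruth:
    block_of: dict[str, int]                      # node -> planted block label
    disease_genes: dict[str, frozenset[str]]      # disease -> its genes
    disease_homes: dict[str, tuple[int, ...]]     # disease -> home blocks
    term_homes: dict[str, int | None]             # term -> home block
    term_members: dict[str, frozenset[str]]
    target_distances: dict[str, dict[str, int]]   # drug -> target -> planted hop bound
    files: dict[str, Path]


def _node_name(block: int, index: int) -> str:
    return f"B{block:02d}N{index:03d}"


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The standard synthetic study: five 100-node blocks, two diseases
    concentrated in blocks 0 and 1, planted enriched terms in each home
    block, one AED-like proximal drug class plus unrelated drugs, and a
    controlled nomination scenario in block 0 (one candidate excluded by
    existing drug coverage, one by tissue expression).
    """
    diseases = (
        DiseaseSpec("RE01", home_blocks=(0,), n_genes=30, leak_rate=0.1),
        DiseaseSpec("RE02", home_blocks=(1,), n_genes=25, leak_rate=0.1),
    )
    terms = []
    for ns in ("BP", "CC", "MF"):
        terms.append(TermSpec(f"{ns}:PLANT0", ns, home_block=0, size=30))
        terms.append(TermSpec(f"{ns}:PLANT1", ns, home_block=1, size=25))
        for i in range(6):
            terms.append(TermSpec(f"{ns}:DECOY{i}", ns, home_block=None, size=40))
    terms.append(TermSpec("PW:PLANT0", "pathway", home_block=0, size=30))
    terms.append(TermSpec("PW:PLANT1", "pathway", home_block=1, size=25))
    for i in range(6):
        terms.append(TermSpec(f"PW:DECOY{i}", "pathway", home_block=None, size=40))
    drugs = (
        DrugSpec("AED01", "AED", n_targets=6, max_hop_to_seed=1),
        DrugSpec("AED02", "AED", n_targets=5, max_hop_to_seed=1),
        DrugSpec("DRUG01", "other", n_targets=6, max_hop_to_seed=None),
        DrugSpec("DRUG02", "other", n_targets=6, max_hop_to_seed=None),
    )
    return SyntheticSpec(
        diseases=diseases,
        terms=tuple(terms),
        drugs=drugs,
        unexpressed_genes=frozenset({_node_name(0, 1)}),
        seed=seed,
    )


def make_nodes(spec: SyntheticSpec) -> dict[str, int]:
    block_of: dict[str, int] = {}
    for b, size in enumerate(spec.block_sizes):
        for i in range(size):
            block_of[_node_name(b, i)] = b
    return block_of


def generate_graph_edges(
    spec: SyntheticSpec, rng: random.Random, block_of: dict[str, int]
) -> list[tuple[str, str, int]]:
    """Planted-partition edges with confidence scores under the score law."""
    nodes = sorted(block_of)
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            within = block_of[u] == block_of[v]
            p = spec.p_within if within else spec.p_between
            if rng.random() < p:
                edges.append((u, v, spec.score_law.draw(rng, within)))
    return edges


def generate(spec: SyntheticSpec, outdir: str | Path) -> GroundTruth:
    """Write all pipeline input files into ``outdir`` and return the truth.

    Files produced: ``ppi_edges.tsv``, ``disease_genes.tsv``, one GMT per
    namespace (``go_bp.gmt``, ``go_cc.gmt``, ``go_mf.gmt``,
    ``pathways.gmt``), ``drug_targets.tsv``, ``expression.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    block_of = make_nodes(spec)
    nodes_by_block = [sorted(n for n, b in block_of.items() if b == blk)
                      for blk in range(spec.n_blocks)]
    all_nodes = sorted(block_of)

    edges = generate_graph_edges(spec, rng, block_of)
    ppi_path = outdir / "ppi_edges.tsv"
    with open(ppi_path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for u, v, s in edges:
            fh.write(f"{u}\t{v}\t{s}\n")

    # disease genes: draw from home blocks, leaking a controlled fraction out
    disease_genes: dict[str, frozenset[str]] = {}
    for d in spec.diseases:
        home_pool = sorted(set().union(*(nodes_by_block[b] for b in d.home_blocks)))
        away_pool = sorted(set(all_nodes) - set(home_pool))
        n_leak = min(round(d.leak_rate * d.n_genes), len(away_pool))
        n_home = d.n_genes - n_leak
        if n_home > len(home_pool):
            raise ValueError(f"{d.disease_id}: home blocks too small for {n_home} genes")
        genes = rng.sample(home_pool, n_home) + rng.sample(away_pool, n_leak)
        disease_genes[d.disease_id] = frozenset(genes)
    dg_path = outdir / "disease_genes.tsv"
    with open(dg_path, "w") as fh:
        fh.write("disease_id\tgene\n")
        for d in spec.diseases:
            for gene in sorted(disease_genes[d.disease_id]):
                fh.write(f"{d.disease_id}\t{gene}\n")

    # annotation terms: planted terms drawn from their home block, decoys uniform
    term_members: dict[str, frozenset[str]] = {}
    term_homes: dict[str, int | None] = {}
    namespaces: dict[str, list[TermSpec]] = {}
    for t in spec.terms:
        namespaces.setdefault(t.namespace, []).append(t)
        pool = nodes_by_block[t.home_block] if t.home_block is not None else all_nodes
        if t.size > len(pool):
            raise ValueError(f"term {t.term_id}: size {t.size} exceeds pool {len(pool)}")
        term_members[t.term_id] = frozenset(rng.sample(sorted(pool), t.size))
        term_homes[t.term_id] = t.home_block
    gmt_names = {"BP": "go_bp.gmt", "CC": "go_cc.gmt", "MF": "go_mf.gmt", "pathway": "pathways.gmt"}
    gmt_paths: dict[str, Path] = {}
    for ns, terms in namespaces.items():
        path = outdir / gmt_names.get(ns, f"{ns}.gmt")
        gmt_paths[ns] = path
        with open(path, "w") as fh:
            for t in terms:
                fh.write("\t".join([t.term_id, f"synthetic {ns} term",
                                    *sorted(term_members[t.term_id])]) + "\n")

    # drug targets: proximal drugs draw from nodes within max_hop of the seed
    # union on the high-confidence subgraph, others uniformly
    all_seeds = set().union(*disease_genes.values()) if disease_genes else set()
    hop_pools: dict[int, list[str]] = {}
    if any(d.max_hop_to_seed is not None for d in spec.drugs) and all_seeds:
        import networkx as nx
        g = nx.Graph((u, v) for u, v, s in edges if s >= 700)
        dist = nx.multi_source_dijkstra_path_length(g, all_seeds & set(g.nodes), weight=None)
        for node, d in dist.items():
            hop_pools.setdefault(d, []).append(node)
    target_distances: dict[str, dict[str, int]] = {}
    pairs: list[tuple[str, str, str]] = []
    for drug in spec.drugs:
        if drug.max_hop_to_seed is None:
            chosen = rng.sample(all_nodes, drug.n_targets)
            target_distances[drug.drug_id] = {t: -1 for t in chosen}
        else:
            pool = sorted(set().union(
                *(hop_pools.get(h, []) for h in range(drug.max_hop_to_seed + 1))
            ))
            if drug.n_targets > len(pool):
                raise ValueError(f"{drug.drug_id}: not enough nodes within "
                                 f"{drug.max_hop_to_seed} hops of the seeds")
            chosen = rng.sample(pool, drug.n_targets)
            dist_of = {t: next(h for h, nodes in hop_pools.items() if t in nodes)
                       for t in chosen}
            target_distances[drug.drug_id] = dist_of
        for t in sorted(chosen):
            pairs.append((drug.drug_id, t, drug.indication_class))
    dt_path = outdir / "drug_targets.tsv"
    with open(dt_path, "w") as fh:
        fh.write("drug_id\ttarget\tclass\n")
        for drug_id, target, cls in pairs:
            fh.write(f"{drug_id}\t{target}\t{cls}\n")

    # expression: every gene expressed in both reference tissues unless
    # explicitly planted unexpressed
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene\ttissue\texpressed\n")
        for gene in all_nodes:
            flag = "no" if gene in spec.unexpressed_genes else "yes"
            fh.write(f"{gene}\tcerebral cortex\t{flag}\n")
            fh.write(f"{gene}\thippocampus\t{flag}\n")

    files = {"ppi": ppi_path, "disease_genes": dg_path, "drug_targets": dt_path,
             "expression": expr_path}
    files.update({f"gmt_{ns}": p for ns, p in gmt_paths.items()})
    return GroundTruth(
        block_of=block_of,
        disease_genes=disease_genes,
        disease_homes={d.disease_id: d.home_blocks for d in spec.diseases},
        term_homes=term_homes,
        term_members=term_members,
        target_distances=target_distances,
        files=files,
    )


def planted_disease_cohort(
    n_modules: int,
    module_size: int,
    n_disease_modules: int,
    density_disease: float,
    density_background: float,
    seed: int,
) -> tuple[list[frozenset[str]], set[str], set[int]]:
    """Membership-only cohort for testing the RR screen.

    Returns (module member sets, seed-gene set, indices of planted disease
    modules).  Each node of a planted module is a seed gene with
    probability ``density_disease``; elsewhere ``density_background``.
    No graph is needed: relative risk depends only on memberships.
    """
    if n_disease_modules > n_modules:
        raise ValueError("more disease modules than modules")
    rng = random.Random(seed)
    members: list[frozenset[str]] = []
    seeds: set[str] = set()
    planted = set(range(n_disease_modules))
    for idx in range(n_modules):
        nodes = [f"C{idx:03d}G{i:03d}" for i in range(module_size)]
        members.append(frozenset(nodes))
        density = density_disease if idx in planted else density_background
        seeds.update(n for n in nodes if rng.random() < density)
    return members, seeds, planted
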