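"""Network proximity of drug targets to disease seed genes.

The distance of a drug-target protein to the disease is the minimum hop
count from the target to any seed gene on the interactome (0 when the
target is itself a seed).  Observed target distances are compared against
randomised protein groups of the same size with a two-sample Student
t-test.  Per-module, targets are censused as direct members or first
neighbours of the module's seed genes, and novel candidate targets are
nominated from a module's top enriched pathway after excluding genes
already targeted by drugs of the indication class under study and genes
not expressed in the required tissues.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy import stats

from .interactome import ParseError
from .modules import ModulePartition

logger = logging.getLogger(__name__)

DEFAULT_NULL_SAMPLES = 100
UNREACHABLE = -1
DEFAULT_REQUIRED_TISSUES = frozenset({"cerebral cortex", "hippocampus"})


@dataclass(frozen=True)
class DrugTargetMap:
    pairs: frozenset[tuple[str, str]]  # (drug_id, target gene)
    indication_class: dict[str, str] = field(default_factory=dict)  # drug_id -> class

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def targets_of(self, drug_id: str) -> frozenset[str]:
        return frozenset(t for d, t in self.pairs if d == drug_id)

    def drugs_of(self, target: str) -> frozenset[str]:
        return frozenset(d for d, t in self.pairs if t == target)

    def drugs_in_class(self, cls: str) -> frozenset[str]:
        return frozenset(d for d, c in self.indication_class.items() if c == cls)


@dataclass(frozen=True)
class ProximityResult:
    distances: dict[str, int]       # mapped target -> min hops to nearest seed
    n_unmapped: int
    n_unreachable: int
    null_distances: list[list[int]] | None = None
    t_statistic: float | None = None
    p_value: float | None = None

    @property
    def observed(self) -> list[int]:
        return [d for d in self.distances.values() if d != UNREACHABLE]


@dataclass(frozen=True)
class ModuleDrugCensus:
    module_id: str
    direct_targets: frozenset[str]
    neighbor_targets: frozenset[str]
    drugs: frozenset[str]
    n_proteins: int

    @property
    def drugs_per_protein(self) -> float:
        return len(self.drugs) / self.n_proteins if self.n_proteins else 0.0


def load_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a ``drug_id<TAB>target<TAB>class`` table (class optional)."""
    pairs: set[tuple[str, str]] = set()
    classes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            if lineno == 1 and fields[0].lower() == "drug_id":
                continue
            drug, target = fields[0], fields[1].strip().upper()
            pairs.add((drug, target))
            if len(fields) >= 3:
                classes[drug] = fields[2]
    return DrugTargetMap(pairs=frozenset(pairs), indication_class=classes)


def load_expression(path: str | Path) -> dict[str, set[str]]:
    """Read a ``gene<TAB>tissue<TAB>expressed`` table into gene -> tissues expressed."""
    expressed: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and fields[0].lower() == "gene":
                continue
            gene, tissue, flag = fields[0].strip().upper(), fields[1].strip().lower(), fields[2].strip().lower()
            if flag in ("yes", "1", "true"):
                expressed.setdefault(gene, set()).add(tissue)
    return expressed


def _distance_to_seeds(g: nx.Graph, seeds: set[str]) -> dict[str, int]:
    mapped_seeds = seeds & set(g.nodes)
    if not mapped_seeds:
        raise ValueError("no seed genes map to the network")
    # one multi-source BFS gives every node's hop distance to its nearest seed
    return dict(nx.multi_source_dijkstra_path_length(g, mapped_seeds, weight=None))


def min_distances(g: nx.Graph, targets: set[str], seeds: set[str]) -> ProximityResult:
    """Minimum hop distance from each mapped target to the nearest seed.

    Targets absent from the network are dropped with a logged count;
    targets in a component with no seed get the unreachable sentinel and
    are excluded from downstream statistics.
    """
    if not targets or not seeds:
        raise ValueError("targets and seeds must be nonempty")
    mapped = sorted(t for t in targets if t in g)
    if not mapped:
        raise ValueError("no drug targets map to the network")
    n_unmapped = len(targets) - len(mapped)
    if n_unmapped:
        logger.info("%d/%d targets not in the network; dropped", n_unmapped, len(targets))
    dist = _distance_to_seeds(g, seeds)
    distances = {t: dist.get(t, UNREACHABLE) for t in mapped}
    n_unreachable = sum(1 for d in distances.values() if d == UNREACHABLE)
    if n_unreachable:
        logger.info("%d mapped targets cannot reach any seed", n_unreachable)
    return ProximityResult(distances=distances, n_unmapped=n_unmapped, n_unreachable=n_unreachable)


def proximity_null(
    g: nx.Graph,
    targets: set[str],
    seeds: set[str],
    n_samples: int = DEFAULT_NULL_SAMPLES,
    seed: int = 0,
    degree_matched: bool = False,
    welch: bool = False,
) -> ProximityResult:
    """Observed target-seed distances versus a randomised null.

    Draws ``n_samples`` random protein sets of the mapped-target size
    (uniform over nodes, or degree-matched by drawing from log-degree bins)
    and compares the observed distances against the pooled null distances
    with a two-sample t-test (pooled variance by default, Welch by flag).
    """
    base = min_distances(g, targets, seeds)
    observed = base.observed
    n_draw = len(base.distances)
    nodes = sorted(g.nodes)
    if n_draw > len(nodes):
        raise ValueError("sample size exceeds network size")
    rng = random.Random(seed)
    dist = _distance_to_seeds(g, seeds)

    bins: dict[int, list[str]] = {}
    if degree_matched:
        for node in nodes:
            bins.setdefault(int(g.degree(node)).bit_length(), []).append(node)

    null_distances: list[list[int]] = []
    for _ in range(n_samples):
        if degree_matched:
            sample = [
                rng.choice(bins[int(g.degree(t)).bit_length()])
                for t in sorted(base.distances)
            ]
        else:
            sample = rng.sample(nodes, n_draw)
        null_distances.append([dist[n] for n in sample if n in dist])

    pooled = [d for sample in null_distances for d in sample]
    if observed and pooled:
        t_stat, p_value = stats.ttest_ind(observed, pooled, equal_var=not welch)
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        t_stat, p_value = 0.0, 1.0
    return ProximityResult(
        distances=base.distances,
        n_unmapped=base.n_unmapped,
        n_unreachable=base.n_unreachable,
        null_distances=null_distances,
        t_statistic=t_stat,
        p_value=p_value,
    )


def module_census(
    g: nx.Graph,
    p: ModulePartition,
    dmap: DrugTargetMap,
    seeds_by_module: dict[str, set[str]],
) -> list[ModuleDrugCensus]:
    """Per-module census of drug targets and distinct drugs.

    Direct targets are drug targets that are module members; neighbour
    targets sit at hop distance exactly 1 from any of the module's own
    seed genes without being members.  Drugs are counted when they have at
    least one direct target in the module.
    """
    targets = dmap.targets & set(g.nodes)
    out = []
    for module in p.modules:
        direct = frozenset(targets & module.members)
        module_seeds = {s for s in seeds_by_module.get(module.module_id, set()) if s in g}
        neighbor_pool: set[str] = set()
        for s in module_seeds:
            neighbor_pool.update(g.neighbors(s))
        neighbors = frozenset((targets & neighbor_pool) - module.members)
        drugs = frozenset(d for d in dmap.drugs if dmap.targets_of(d) & direct)
        out.append(
            ModuleDrugCensus(
                module_id=module.module_id,
                direct_targets=direct,
                neighbor_targets=neighbors,
                drugs=drugs,
                n_proteins=module.size,
            )
        )
    return out


def nominate_targets(
    module_members: set[str],
    module_top_pathway_genes: set[str],
    dmap: DrugTargetMap,
    aed_drug_ids: set[str],
    expression: dict[str, set[str]] | None = None,
    required_tissues: frozenset[str] = DEFAULT_REQUIRED_TISSUES,
) -> list[str]:
    """Nominate novel candidate targets within one disease module.

    A candidate must (1) be a module member lying in the module's most
    enriched pathway, (2) not already be targeted by any drug of the
    disease's own indication class (``aed_drug_ids``), and (3) when an
    expression table is given, be expressed in at least one of the
    required tissues.
    """
    if not module_top_pathway_genes:
        logger.warning("empty top pathway; no candidates nominated")
        return []
    aed_targets: set[str] = set()
    for drug in aed_drug_ids:
        aed_targets |= dmap.targets_of(drug)
    candidates = (module_members & module_top_pathway_genes) - aed_targets
    if expression is not None:
        tissues = {t.lower() for t in required_tissues}
        candidates = {
            gene for gene in candidates
            if expression.get(gene, set()) & tissues
        }
    return sorted(candidates)


def write_census(census: list[ModuleDrugCensus], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_id\tn_proteins\tdirect_targets\tneighbor_targets\tn_drugs\tdrugs_per_protein\n")
        for c in census:
            fh.write(
                f"{c.module_id}\t{c.n_proteins}\t{len(c.direct_targets)}\t"
                f"{len(c.neighbor_targets)}\t{len(c.drugs)}\t{c.drugs_per_protein:.6g}\n"
            )
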