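"""Functional similarity between modules from their enrichment profiles.

Each module gets, per namespace, a vector over annotation terms whose
entries are ``-log(corrected p)`` for the module's significant terms and 0
elsewhere.  Module pairs are compared by cosine similarity within each
namespace, and the per-namespace similarities are merged into a combined
score that weights the three GO namespaces and the pathway namespace
equally:

    combined = 0.5 * (sim_BP + sim_CC + sim_MF) / 3 + 0.5 * sim_pathway

Modules are then clustered on the thresholded combined-score graph by
modularity maximisation; modules with no similarity edge stay unclustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .enrichment import DEFAULT_ALPHA, EnrichmentRecord

#: Corrected p-values are floored here before taking the log so that
#: underflowed (reported-as-zero) p-values map to a finite profile entry.
P_FLOOR = 1e-300

DEFAULT_MIN_COMBINED = 0.05


@dataclass(frozen=True)
class FunctionalProfile:
    module_id: str
    namespace: str
    vector: dict[str, float]  # term_id -> -log(p_corrected), significant terms only

    def __post_init__(self) -> None:
        for term, value in self.vector.items():
            if not (value >= 0 and math.isfinite(value)):
                raise ValueError(f"profile entry {term} = {value} is not finite/non-negative")


@dataclass(frozen=True)
class SimilarityRecord:
    module_a: str
    module_b: str
    sim_bp: float
    sim_cc: float
    sim_mf: float
    sim_pathway: float
    combined: float


def build_profile(
    module_id: str,
    namespace: str,
    records: list[EnrichmentRecord],
    alpha: float = DEFAULT_ALPHA,
) -> FunctionalProfile:
    """Profile vector from a module's enrichment records in one namespace.

    Only significant terms (corrected p < alpha) contribute; their entry is
    the natural -log of the corrected p, floored at ``P_FLOOR``.
    """
    vector = {
        r.term_id: -math.log(max(r.p_corrected, P_FLOOR))
        for r in records
        if r.module_id == module_id and r.namespace == namespace and r.p_corrected < alpha
    }
    return FunctionalProfile(module_id=module_id, namespace=namespace, vector=vector)


def cosine(a: FunctionalProfile, b: FunctionalProfile) -> float:
    """Cosine similarity over the union of the two term spaces.

    Absent terms contribute 0; an all-zero vector has similarity 0 by
    convention.  Entries are non-negative, so the result is in [0, 1].
    """
    if a.namespace != b.namespace:
        raise ValueError(f"namespace mismatch: {a.namespace} vs {b.namespace}")
    dot = sum(value * b.vector.get(term, 0.0) for term, value in a.vector.items())
    norm_a = math.sqrt(sum(v * v for v in a.vector.values()))
    norm_b = math.sqrt(sum(v * v for v in b.vector.values()))
    if norm_a == 0.0 or norm_b == 0.0:
        return 0.0
    return min(1.0, dot / (norm_a * norm_b))


def combined_score(sim_bp: float, sim_cc: float, sim_mf: float, sim_pathway: float) -> float:
    """Equal-weight merge of GO and pathway similarities.

    Half the weight goes to the mean of the three GO-namespace similarities
    and half to the pathway similarity.
    """
    for name, value in (("BP", sim_bp), ("CC", sim_cc), ("MF", sim_mf), ("pathway", sim_pathway)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} similarity {value} outside [0, 1]")
    return 0.5 * ((sim_bp + sim_cc + sim_mf) / 3.0) + 0.5 * sim_pathway


def pairwise_similarity(
    profiles: dict[str, dict[str, FunctionalProfile]],
) -> list[SimilarityRecord]:
    """All-pairs similarity records from per-module, per-namespace profiles.

    ``profiles`` maps module_id -> namespace -> profile.  A module missing
    a namespace contributes an empty profile (similarity 0) there.
    """
    module_ids = sorted(profiles)
    records = []
    for i, ma in enumerate(module_ids):
        for mb in module_ids[i + 1:]:
            sims = {}
            for ns in ("BP", "CC", "MF", "pathway"):
                pa = profiles[ma].get(ns) or FunctionalProfile(ma, ns, {})
                pb = profiles[mb].get(ns) or FunctionalProfile(mb, ns, {})
                sims[ns] = cosine(pa, pb)
            records.append(
                SimilarityRecord(
                    module_a=ma, module_b=mb,
                    sim_bp=sims["BP"], sim_cc=sims["CC"], sim_mf=sims["MF"],
                    sim_pathway=sims["pathway"],
                    combined=combined_score(sims["BP"], sims["CC"], sims["MF"], sims["pathway"]),
                )
            )
    records.sort(key=lambda r: (-r.combined, r.module_a, r.module_b))
    return records


def cluster_modules(
    records: list[SimilarityRecord],
    min_combined: float = DEFAULT_MIN_COMBINED,
    seed: int = 0,
) -> tuple[dict[str, int], list[str]]:
    """Modularity clustering of the thresholded combined-score graph.

    Returns (module_id -> cluster index, unclustered module_ids): modules
    with no retained similarity edge are reported separately rather than
    forced into singleton clusters.
    """
    g = nx.Graph()
    all_modules = set()
    for r in records:
        all_modules.update((r.module_a, r.module_b))
        if r.combined >= min_combined:
            g.add_edge(r.module_a, r.module_b, weight=r.combined)
    unclustered = sorted(all_modules - set(g.nodes))
    if g.number_of_edges() == 0:
        return {}, sorted(all_modules)
    comms = louvain_communities(g, weight="weight", seed=seed)
    assignment: dict[str, int] = {}
    for idx, comm in enumerate(sorted(comms, key=min)):
        for mid in sorted(comm):
            assignment[mid] = idx
    return assignment, unclustered


def write_similarity(records: list[SimilarityRecord], path, header: str | None = None) -> None:
    """Long-format TSV: Module1, Module2, GO-BP, GO-MF, GO-CC, Pathway, Combined."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("Module1\tModule2\tGO-BP\tGO-MF\tGO-CC\tPathway\tCombined\n")
        for r in records:
            fh.write(
                f"{r.module_a}\t{r.module_b}\t{r.sim_bp:.4g}\t{r.sim_mf:.4g}\t"
                f"{r.sim_cc:.4g}\t{r.sim_pathway:.4g}\t{r.combined:.3f}\n"
            )
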