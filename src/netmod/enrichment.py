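"""Hypergeometric over-representation analysis with Bonferroni correction.

Gene sets come in GMT files (``term_id<TAB>description<TAB>gene1<TAB>...``),
one collection per namespace (GO biological process / cellular component /
molecular function, or pathways).  For a query gene set of size ``n``
(restricted to the collection's annotated universe of size ``N``), a term
annotating ``K`` genes with ``k`` of them in the query scores the
upper-tail hypergeometric probability P(X >= k).  Bonferroni multiplies by
the number of tests, by default the number of terms with nonzero overlap
for this query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from scipy import stats

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF", "pathway")
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSetCollection:
    namespace: str
    sets: dict[str, tuple[str, frozenset[str]]]  # term_id -> (description, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.sets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {term_id} has genes outside the universe: {sorted(extra)[:5]}")


@dataclass(frozen=True)
class EnrichmentRecord:
    module_id: str
    term_id: str
    namespace: str
    description: str
    k: int  # overlap
    n: int  # annotated query size
    K: int  # term size
    N: int  # universe size
    p_raw: float
    p_corrected: float
    significant: bool


def load_gmt(path: str | Path, namespace: str, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file.

    When ``universe`` is omitted it defaults to the union of all member
    genes in the file (the annotated-gene universe).
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            term_id, description = fields[0], fields[1]
            if term_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id}")
            genes = frozenset(gene.strip().upper() for gene in fields[2:] if gene.strip())
            sets[term_id] = (description, genes)
    if universe is None:
        universe = set().union(*(genes for _, genes in sets.values())) if sets else set()
    return GeneSetCollection(namespace=namespace, sets=sets, universe=frozenset(universe))


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(coll.sets):
            description, genes = coll.sets[term_id]
            fh.write("\t".join([term_id, description, *sorted(genes)]) + "\n")


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them annotated to the term,
    ``n`` drawn (the query); the upper tail is the enrichment p-value.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_module(
    module_id: str,
    members: set[str],
    coll: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    bonferroni_all_terms: bool = False,
    universe_override: set[str] | None = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of a module against one collection.

    The query is ``members`` intersected with the universe.  One record is
    produced per term with nonzero overlap; the Bonferroni factor is the
    number of such terms (or all terms in the collection when
    ``bonferroni_all_terms``).  Records are sorted by corrected p, ties by
    term_id.
    """
    universe = frozenset(universe_override) if universe_override is not None else coll.universe
    query = frozenset(g.upper() for g in members) & universe
    if not query:
        logger.warning("module %s has no genes annotated in namespace %s", module_id, coll.namespace)
        return []
    n, N = len(query), len(universe)

    hits = []
    for term_id, (description, genes) in coll.sets.items():
        term_genes = genes & universe
        k = len(query & term_genes)
        if k >= 1:
            hits.append((term_id, description, k, len(term_genes)))
    m = len(coll.sets) if bonferroni_all_terms else len(hits)
    logger.debug("module %s namespace %s: %d terms tested (Bonferroni m=%d)",
                 module_id, coll.namespace, len(hits), m)

    records = []
    for term_id, description, k, K in hits:
        p_raw = hypergeom_upper(k, n, K, N)
        p_corrected = min(1.0, p_raw * m)
        records.append(
            EnrichmentRecord(
                module_id=module_id,
                term_id=term_id,
                namespace=coll.namespace,
                description=description,
                k=k, n=n, K=K, N=N,
                p_raw=p_raw,
                p_corrected=p_corrected,
                significant=p_corrected < alpha,
            )
        )
    records.sort(key=lambda r: (r.p_corrected, r.term_id))
    return records


def top_term(records: list[EnrichmentRecord], namespace: str) -> EnrichmentRecord | None:
    """The minimum-corrected-p record of the given namespace, or None."""
    candidates = [r for r in records if r.namespace == namespace]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (r.p_corrected, r.term_id))


def write_enrichment(records: list[EnrichmentRecord], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_id\tterm_id\tnamespace\tdescription\tk\tn\tK\tN\tp_raw\tp_corrected\tsignificant\n")
        for r in records:
            fh.write(
                f"{r.module_id}\t{r.term_id}\t{r.namespace}\t{r.description}\t"
                f"{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_raw:.6g}\t{r.p_corrected:.6g}\t{int(r.significant)}\n"
            )
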