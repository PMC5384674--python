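"""Disease-gene association tables and external-reference validation.

A disease-gene map is the bipartite association between disease subtypes
(e.g. MeSH headings) and curated seed genes.  Besides simple loading and
per-gene multiplicity counts, the module validates a curated gene list
against an independent reference list (e.g. phenotype-ontology genes) by
fold enrichment over random expectation with a one-sided binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats

from .interactome import ParseError

logger = logging.getLogger(__name__)

#: Default gene universe for the binomial validation test: the approximate
#: number of human protein-coding genes.  Exposed as a required parameter
#: because fold enrichment scales directly with it.
DEFAULT_UNIVERSE_SIZE = 19_063


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Deduplicated set of (disease_id, gene) association pairs."""

    associations: frozenset[tuple[str, str]]
    diseases: frozenset[str] = field(init=False)
    genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", frozenset(d for d, _ in self.associations))
        object.__setattr__(self, "genes", frozenset(g for _, g in self.associations))

    def genes_of(self, disease_id: str) -> frozenset[str]:
        return frozenset(g for d, g in self.associations if d == disease_id)


@dataclass(frozen=True)
class OverlapValidation:
    """Fold enrichment of an observed overlap over random expectation."""

    n_overlap: int
    n_reference: int
    fold: float
    p_value: float
    universe_size: int


def load_disease_genes(path: str | Path) -> DiseaseGeneMap:
    """Read a delimited ``disease_id<TAB>gene`` table.

    A header line whose first field is ``disease_id`` (case-insensitive) is
    skipped.  Extra columns (disease metadata) are ignored.  Duplicate
    pairs are collapsed.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            if lineno == 1 and fields[0].lower() == "disease_id":
                continue
            pairs.add((fields[0], fields[1].strip().upper()))
    m = DiseaseGeneMap(frozenset(pairs))
    if not pairs:
        logger.warning("%s: no disease-gene associations found", path)
    logger.info(
        "loaded %d associations: %d diseases x %d genes",
        len(m.associations), len(m.diseases), len(m.genes),
    )
    return m


def gene_multiplicity(m: DiseaseGeneMap) -> dict[str, int]:
    """Number of distinct diseases each gene is associated with."""
    counts: dict[str, int] = {}
    for _, gene in m.associations:
        counts[gene] = counts.get(gene, 0) + 1
    return counts


def multiplicity_histogram(m: DiseaseGeneMap) -> dict[int, int]:
    """Histogram of disease counts per gene (how many genes map to k diseases)."""
    hist: dict[int, int] = {}
    for count in gene_multiplicity(m).values():
        hist[count] = hist.get(count, 0) + 1
    return hist


def validate_against_reference(
    genes: set[str],
    reference: set[str],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> OverlapValidation:
    """Fold enrichment of ``genes`` against an independent reference list.

    The expected overlap under random draws is
    ``|reference| * |genes| / universe_size``; fold is the ratio of the
    observed overlap to that expectation.  Significance is the upper-tail
    binomial probability of at least the observed overlap when each of the
    ``|reference|`` genes independently lands in ``genes`` with probability
    ``|genes| / universe_size``.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if universe_size < len(genes | reference):
        raise ValueError("universe_size smaller than the union of the two gene lists")
    n_overlap = len(genes & reference)
    n_reference = len(reference)
    expected = n_reference * len(genes) / universe_size
    fold = n_overlap / expected if expected > 0 else 0.0
    if n_reference == 0:
        p_value = 1.0
    else:
        p_value = float(
            stats.binom.sf(n_overlap - 1, n_reference, len(genes) / universe_size)
        )
    return OverlapValidation(
        n_overlap=n_overlap,
        n_reference=n_reference,
        fold=fold,
        p_value=p_value,
        universe_size=universe_size,
    )
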