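"""Weighted protein-protein interaction (PPI) network I/O.

The interactome is an undirected graph whose nodes are protein identifiers
(gene symbols, normalised to uppercase) and whose edges carry an integer
confidence score in [0, 1000], following the STRING "protein links" dialect:
one interaction per line, ``proteinA proteinB score``, whitespace-delimited,
with an optional header line.  Scores >= 700 are conventionally treated as
the high-confidence subset; the threshold here is inclusive and
configurable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx

logger = logging.getLogger(__name__)

SCORE_MIN = 0
SCORE_MAX = 1000


class ParseError(ValueError):
    """Raised when an edge-list or table line cannot be interpreted."""


def _normalize(identifier: str, aliases: Mapping[str, str] | None = None) -> str:
    name = identifier.strip().upper()
    if aliases is not None:
        name = aliases.get(name, name)
    return name


def load_aliases(path: str | Path) -> dict[str, str]:
    """Read a two-column ``old<TAB>new`` identifier mapping.

    Both columns are uppercased; later lines override earlier ones.
    """
    aliases: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            aliases[fields[0].upper()] = fields[1].upper()
    return aliases


def load_interactome(
    path: str | Path,
    score_threshold: int = 700,
    aliases: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a weighted edge list and keep edges with score >= threshold.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file with lines ``idA idB score``.
        A single header line is skipped automatically when its third field
        is not an integer.
    score_threshold
        Inclusive lower bound on the confidence score, in [0, 1000].
    aliases
        Optional identifier mapping applied after uppercasing.

    Returns
    -------
    networkx.Graph
        Edges carry a ``score`` attribute.  Duplicate lines (in either
        orientation) are collapsed keeping the maximum score; self-loops
        are dropped with a logged count.
    """
    if not (SCORE_MIN <= score_threshold <= SCORE_MAX):
        raise ValueError(f"score_threshold must be in [0, 1000], got {score_threshold}")

    g = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            try:
                score = int(fields[2])
            except ValueError:
                if lineno == 1:  # header line, third field non-numeric
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-integer score {fields[2]!r}"
                ) from None
            if not (SCORE_MIN <= score <= SCORE_MAX):
                raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            a = _normalize(fields[0], aliases)
            b = _normalize(fields[1], aliases)
            if a == b:
                n_self_loops += 1
                continue
            if score < score_threshold:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)

    if n_self_loops:
        logger.info("dropped %d self-loop line(s)", n_self_loops)
    if g.number_of_edges() == 0:
        logger.warning(
            "no edges passed the score threshold %d; returning an empty graph",
            score_threshold,
        )
    logger.info(
        "loaded %d proteins / %d interactions (threshold %d)",
        g.number_of_nodes(), g.number_of_edges(), score_threshold,
    )
    return g


def write_interactome(g: nx.Graph, path: str | Path) -> None:
    """Write the edge list back out, one ``idA idB score`` line per edge.

    Edges are emitted in sorted order so that writing is deterministic and
    a load/write/load round trip reproduces the graph exactly.
    """
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\t{g[a][b]['score']}\n")


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken by the lexicographically smallest
    member node, so the result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty graph")
    best = min(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(best).copy()
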