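"""Disease-module association by relative risk and chi-square.

A module of ``m`` proteins containing ``k`` disease seed genes, against a
background of ``S`` mapped seed genes among ``N`` proteins distributed in
modules, has relative risk

    RR = (k / m) / (S / N)

— the in-module seed density over the background density.  Significance
uses the chi-square statistic of the 2x2 table
``[[k, m-k], [S-k, N-m-(S-k)]]`` with 1 degree of freedom, Bonferroni
corrected across the modules tested.  The background (S, N) covers only
proteins inside analysed modules, not the full interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .disease_genes import DiseaseGeneMap
from .modules import ModulePartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleDiseaseStats:
    module_id: str
    m: int       # module size
    k: int       # seed genes in the module
    S: int       # total mapped seed genes
    N: int       # total proteins in analysed modules
    rr: float
    chi2: float
    p_raw: float
    p_corrected: float


@dataclass(frozen=True)
class DiseaseModuleMap:
    """(disease_id, module_id, rr) triples with rr over the threshold."""

    pairs: tuple[tuple[str, str, float], ...]
    rr_threshold: float

    def modules_of(self, disease_id: str) -> list[str]:
        return [mid for d, mid, _ in self.pairs if d == disease_id]


def _chi2_2x2(k: int, m: int, S: int, N: int, yates: bool = False) -> tuple[float, float]:
    """Chi-square statistic and p for the 2x2 seed-by-module table.

    Computed directly as sum((O-E)^2 / E) over the four cells; returns
    (0, 1) when any expected count is zero (degenerate margin).
    """
    observed = [[k, m - k], [S - k, N - m - (S - k)]]
    row = [m, N - m]
    col = [S, N - S]
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / N
            if expected == 0:
                return 0.0, 1.0
            diff = abs(observed[i][j] - expected)
            if yates:
                diff = max(0.0, diff - 0.5)
            chi2 += diff * diff / expected
    return chi2, float(stats.chi2.sf(chi2, df=1))


def module_rr(
    module_id: str,
    members: set[str],
    seeds: set[str],
    S: int,
    N: int,
    n_tests: int = 1,
    yates: bool = False,
) -> ModuleDiseaseStats:
    """Relative risk and chi-square of one module against the seed set.

    ``S`` and ``N`` are the background: total mapped seed genes and total
    proteins in analysed modules.  ``n_tests`` is the Bonferroni factor
    (number of modules tested in the screen this stat belongs to).
    """
    m = len(members)
    k = len(members & seeds)
    if m < 1:
        raise ValueError("empty module")
    if S <= 0 or N <= 0:
        raise ValueError("background S and N must be positive")
    if N < m or S < k:
        raise ValueError(f"inconsistent background: k={k}, m={m}, S={S}, N={N}")
    rr = (k / m) / (S / N)
    chi2, p_raw = _chi2_2x2(k, m, S, N, yates=yates)
    return ModuleDiseaseStats(
        module_id=module_id, m=m, k=k, S=S, N=N,
        rr=rr, chi2=chi2, p_raw=p_raw,
        p_corrected=min(1.0, p_raw * n_tests),
    )


def score_modules(
    p: ModulePartition,
    seeds: set[str],
    min_size: int = 1,
    yates: bool = False,
) -> list[ModuleDiseaseStats]:
    """RR / chi-square screen over all modules containing >= 1 seed gene.

    The background (S, N) is computed from the analysed modules themselves:
    N is their total membership and S the seed genes falling inside them.
    Bonferroni correction is across the modules actually tested (k >= 1).
    """
    analysed = [m for m in p.modules if m.size >= min_size]
    N = sum(m.size for m in analysed)
    S = sum(len(m.members & seeds) for m in analysed)
    if S == 0:
        logger.warning("no seed genes map into the analysed modules")
        return []
    tested = [m for m in analysed if m.members & seeds]
    stats_list = [
        module_rr(m.module_id, set(m.members), seeds, S, N, n_tests=len(tested), yates=yates)
        for m in tested
    ]
    stats_list.sort(key=lambda s: (-s.rr, s.module_id))
    return stats_list


def select_disease_modules(
    stats_list: list[ModuleDiseaseStats],
    rr_threshold: float | None = None,
    threshold_from_module: str | None = None,
) -> list[ModuleDiseaseStats]:
    """Modules passing the RR filter, sorted by RR descending.

    The threshold is either given directly or anchored to a named module's
    own RR (``threshold_from_module``), mirroring the practice of using the
    last chi-square-significant module as the cutoff.
    """
    if not stats_list:
        raise ValueError("no module statistics to filter")
    if (rr_threshold is None) == (threshold_from_module is None):
        raise ValueError("give exactly one of rr_threshold / threshold_from_module")
    if threshold_from_module is not None:
        anchors = [s for s in stats_list if s.module_id == threshold_from_module]
        if not anchors:
            raise ValueError(f"anchor module {threshold_from_module} not in statistics")
        rr_threshold = anchors[0].rr
    selected = [s for s in stats_list if s.rr >= rr_threshold]
    selected.sort(key=lambda s: (-s.rr, s.module_id))
    return selected


def disease_to_modules(
    dmap: DiseaseGeneMap,
    p: ModulePartition,
    rr_threshold: float = 1.0,
    min_size: int = 1,
) -> DiseaseModuleMap:
    """Per-disease module association: modules with rr > threshold and k >= 1.

    Each disease's own mapped gene count serves as its background S.
    """
    analysed = [m for m in p.modules if m.size >= min_size]
    N = sum(m.size for m in analysed)
    pairs: list[tuple[str, str, float]] = []
    for disease_id in sorted(dmap.diseases):
        genes = dmap.genes_of(disease_id)
        S = sum(len(m.members & genes) for m in analysed)
        if S == 0:
            logger.warning("disease %s has no genes mapped into modules", disease_id)
            continue
        for m in analysed:
            k = len(m.members & genes)
            if k == 0:
                continue
            rr = (k / m.size) / (S / N)
            if rr > rr_threshold:
                pairs.append((disease_id, m.module_id, rr))
    return DiseaseModuleMap(pairs=tuple(pairs), rr_threshold=rr_threshold)


def jaccard_between_diseases(dmap: DiseaseGeneMap) -> dict[tuple[str, str], float]:
    """Jaccard similarity of gene sets for every unordered disease pair."""
    diseases = sorted(dmap.diseases)
    if len(diseases) < 2:
        raise ValueError("need at least two diseases")
    gene_sets = {d: dmap.genes_of(d) for d in diseases}
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            union = gene_sets[a] | gene_sets[b]
            out[(a, b)] = len(gene_sets[a] & gene_sets[b]) / len(union) if union else 0.0
    return out


def write_module_stats(stats_list: list[ModuleDiseaseStats], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_id\tm\tk\tS\tN\trr\tchi2\tp_raw\tp_corrected\n")
        for s in stats_list:
            fh.write(
                f"{s.module_id}\t{s.m}\t{s.k}\t{s.S}\t{s.N}\t"
                f"{s.rr:.6g}\t{s.chi2:.6g}\t{s.p_raw:.6g}\t{s.p_corrected:.6g}\n"
            )
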