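"""End-to-end orchestration: load, detect, associate, enrich, compare, nominate.

One flat configuration drives the whole analysis; every output file names
the configuration hash and seed in a header comment line so a run can be
audited and reproduced.  Stages run in the order: interactome loading,
module detection, disease-module association, enrichment, functional
similarity and clustering, drug-target proximity, candidate nomination.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import (
    disease_genes as dg,
    disease_modules as dm,
    drug_targets as dt,
    enrichment as en,
    interactome as io,
    modules as md,
    similarity as sim,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    ppi_path: str
    disease_gene_path: str
    gmt_paths: dict[str, str]          # namespace -> GMT file
    drug_target_path: str | None = None
    expression_path: str | None = None
    output_dir: str = "netmod_out"
    score_threshold: int = 700
    restrict_to_largest_component: bool = False
    min_module_size: int = 5
    max_module_size: int = 400
    alpha: float = 0.05
    bonferroni_all_terms: bool = False
    rr_threshold: float | None = None
    rr_anchor_module: str | None = None
    min_combined: float = sim.DEFAULT_MIN_COMBINED
    null_samples: int = 100
    aed_class: str = "AED"
    required_tissues: tuple[str, ...] = ("cerebral cortex", "hippocampus")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.score_threshold <= 1000:
            raise ValueError("score_threshold outside [0, 1000]")
        if not self.max_module_size > self.min_module_size >= 1:
            raise ValueError("need max_module_size > min_module_size >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "required_tissues" in raw:
            raw["required_tissues"] = tuple(raw["required_tissues"])
        return cls(**raw)

    def digest(self) -> str:
        # identifies the analysis, not where it is written
        payload = asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    partition: md.ModulePartition
    module_stats: list[dm.ModuleDiseaseStats]
    selected: list[dm.ModuleDiseaseStats]
    enrichment_records: list[en.EnrichmentRecord]
    similarity_records: list[sim.SimilarityRecord]
    clusters: dict[str, int]
    unclustered: list[str]
    proximity: dt.ProximityResult | None
    census: list[dt.ModuleDrugCensus]
    nominated: dict[str, list[str]]  # module_id -> candidates
    outputs: dict[str, Path] = field(default_factory=dict)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the per-stage TSVs and summary.

    Any stage failure propagates with the stage name prepended; outputs
    written before the failure are left in place.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config={config.digest()} seed={config.seed}"
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load_interactome")
        g = io.load_interactome(config.ppi_path, config.score_threshold)
        if g.number_of_edges() == 0:
            raise ValueError("no interactions passed the score threshold")
        if config.restrict_to_largest_component:
            g = io.largest_component(g)
    except Exception as exc:
        raise RuntimeError(f"stage load_interactome failed: {exc}") from exc

    try:
        stage("detect_modules")
        partition = md.detect_modules(
            g, max_size=config.max_module_size, min_size=config.min_module_size,
            seed=config.seed,
        )
        outputs["membership"] = outdir / "module_membership.tsv"
        md.write_membership(partition, outputs["membership"], header=tag)
        mg = md.module_graph(g, partition)
        outputs["module_graph"] = outdir / "module_graph.tsv"
        md.write_module_graph(mg, outputs["module_graph"], header=tag)
    except Exception as exc:
        raise RuntimeError(f"stage detect_modules failed: {exc}") from exc

    try:
        stage("disease_modules")
        dmap = dg.load_disease_genes(config.disease_gene_path)
        seeds = set(dmap.genes)
        module_stats = dm.score_modules(partition, seeds, min_size=config.min_module_size)
        if config.rr_anchor_module is not None:
            selected = dm.select_disease_modules(
                module_stats, threshold_from_module=config.rr_anchor_module)
        else:
            threshold = config.rr_threshold if config.rr_threshold is not None else 1.0
            selected = dm.select_disease_modules(module_stats, rr_threshold=threshold)
        outputs["module_stats"] = outdir / "module_disease_stats.tsv"
        dm.write_module_stats(module_stats, outputs["module_stats"], header=tag)
        outputs["selected_modules"] = outdir / "selected_disease_modules.tsv"
        dm.write_module_stats(selected, outputs["selected_modules"], header=tag)
    except Exception as exc:
        raise RuntimeError(f"stage disease_modules failed: {exc}") from exc

    try:
        stage("enrichment")
        collections = {
            ns: en.load_gmt(path, ns) for ns, path in sorted(config.gmt_paths.items())
        }
        records: list[en.EnrichmentRecord] = []
        selected_ids = [s.module_id for s in selected]
        for module_id in selected_ids:
            members = set(partition.by_id(module_id).members)
            for ns, coll in collections.items():
                records.extend(
                    en.enrich_module(
                        module_id, members, coll, alpha=config.alpha,
                        bonferroni_all_terms=config.bonferroni_all_terms,
                    )
                )
        outputs["enrichment"] = outdir / "enrichment.tsv"
        en.write_enrichment(records, outputs["enrichment"], header=tag)
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    try:
        stage("similarity")
        profiles: dict[str, dict[str, sim.FunctionalProfile]] = {}
        for module_id in selected_ids:
            profiles[module_id] = {
                ns: sim.build_profile(module_id, ns, records, alpha=config.alpha)
                for ns in collections
            }
        sim_records = sim.pairwise_similarity(profiles)
        clusters, unclustered = sim.cluster_modules(
            sim_records, min_combined=config.min_combined, seed=config.seed)
        outputs["similarity"] = outdir / "module_similarity.tsv"
        sim.write_similarity(sim_records, outputs["similarity"], header=tag)
        outputs["clusters"] = outdir / "module_clusters.tsv"
        with open(outputs["clusters"], "w") as fh:
            fh.write(f"# {tag}\nmodule_id\tcluster\n")
            for mid in sorted(clusters):
                fh.write(f"{mid}\t{clusters[mid]}\n")
            for mid in unclustered:
                fh.write(f"{mid}\tunclustered\n")
    except Exception as exc:
        raise RuntimeError(f"stage similarity failed: {exc}") from exc

    proximity = None
    census: list[dt.ModuleDrugCensus] = []
    nominated: dict[str, list[str]] = {}
    if config.drug_target_path is not None:
        try:
            stage("drug_targets")
            drug_map = dt.load_drug_targets(config.drug_target_path)
            proximity = dt.proximity_null(
                g, set(drug_map.targets), seeds,
                n_samples=config.null_samples, seed=config.seed,
            )
            seeds_by_module = {
                m.module_id: set(m.members & seeds) for m in partition.modules
            }
            census = dt.module_census(g, partition, drug_map, seeds_by_module)
            outputs["census"] = outdir / "module_drug_census.tsv"
            dt.write_census(census, outputs["census"], header=tag)

            expression = (dt.load_expression(config.expression_path)
                          if config.expression_path else None)
            aed_ids = set(drug_map.drugs_in_class(config.aed_class))
            for module_id in selected_ids:
                pathway_top = en.top_term(
                    [r for r in records if r.module_id == module_id], "pathway")
                if pathway_top is None or not pathway_top.significant:
                    continue
                _, top_genes = collections["pathway"].sets[pathway_top.term_id]
                candidates = dt.nominate_targets(
                    set(partition.by_id(module_id).members),
                    set(top_genes), drug_map, aed_ids,
                    expression=expression,
                    required_tissues=frozenset(config.required_tissues),
                )
                if candidates:
                    nominated[module_id] = candidates
            outputs["candidates"] = outdir / "nominated_targets.tsv"
            with open(outputs["candidates"], "w") as fh:
                fh.write(f"# {tag}\nmodule_id\tcandidate\n")
                for mid in sorted(nominated):
                    for gene in nominated[mid]:
                        fh.write(f"{mid}\t{gene}\n")
        except Exception as exc:
            raise RuntimeError(f"stage drug_targets failed: {exc}") from exc

    try:
        stage("summary")
        outputs["summary"] = outdir / "summary.tsv"
        with open(outputs["summary"], "w") as fh:
            fh.write(f"# {tag}\nkey\tvalue\n")
            fh.write(f"proteins\t{g.number_of_nodes()}\n")
            fh.write(f"interactions\t{g.number_of_edges()}\n")
            fh.write(f"modules\t{len(partition.modules)}\n")
            fh.write(f"modules_small\t{sum(m.small for m in partition.modules)}\n")
            fh.write(f"disease_modules\t{len(selected)}\n")
            fh.write(f"enrichment_records\t{len(records)}\n")
            fh.write(f"clusters\t{len(set(clusters.values()))}\n")
            if proximity is not None:
                fh.write(f"proximity_t\t{proximity.t_statistic:.6g}\n")
                fh.write(f"proximity_p\t{proximity.p_value:.6g}\n")
            fh.write(f"nominated\t{sum(len(v) for v in nominated.values())}\n")
    except Exception as exc:
        raise RuntimeError(f"stage summary failed: {exc}") from exc

    return PipelineResult(
        partition=partition,
        module_stats=module_stats,
        selected=selected,
        enrichment_records=records,
        similarity_records=sim_records,
        clusters=clusters,
        unclustered=unclustered,
        proximity=proximity,
        census=census,
        nominated=nominated,
        outputs=outputs,
    )
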