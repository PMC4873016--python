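"""End-to-end pipeline: rank -> build -> areas -> mine -> filter -> validate.

Each stage is a plain function over the library types; :func:`run_all`
chains them over a fixture-layout input directory, writes every
intermediate as TSV and emits a machine-readable run manifest (config,
per-stage counts, versions — no timestamps, so reruns are byte-identical).
Per-stage timings go to the stderr log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .area_scoring import SIZE_FACTOR_MODES, SIZE_FACTOR_RATIO, AreaScore, score_areas
from .filters import (
    CascadeResult,
    FilterConfig,
    load_action_sets,
    load_adme_genes,
    run_cascade,
)
from .gd_ranking import (
    GoldSelection,
    RankingConfig,
    ScoredAssociation,
    SourceEvidence,
    map_to_mesh,
    per_source_lls,
    score_all,
    select_gold_standard,
    tune_D,
)
from .graph_model import (
    COMMON_DISEASE,
    GENE,
    PROTEIN,
    RARE_DISEASE,
    SMALL_MOLECULE,
    SemanticGraph,
    merge_rare_disease_synonyms,
    save_graph,
)
from .mesh_sim import MeshTree, SimParams
from .mining import InferredIndication, SubgraphMapping, candidate_drugs, dedupe, find_mappings
from .validation import ValidationReport, evaluate

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide settings; the defaults reproduce the published operating
    point (D = 5.0, ET = 0.768, validation Sim = 0.633, hierarchy depth 10)."""

    d: float = 5.0
    tune_d: bool = False
    equivalence_threshold: float = 0.768
    validation_sim: float = 0.633
    sim_depth: int = 10
    size_factor_mode: str = SIZE_FACTOR_RATIO
    # prior odds over every gene x disease combination captured in the data;
    # the magnitude of published per-source log-likelihood scores is only
    # attainable under this reading (a captured-pairs-only prior is available
    # via "captured")
    universe: str = "cartesian"
    zero_cell_policy: str = "error"
    n_areas_reference: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_factor_mode not in SIZE_FACTOR_MODES:
            raise ValueError(f"unknown size-factor mode {self.size_factor_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def ranking_config(self) -> RankingConfig:
        return RankingConfig(
            D=self.d, zero_cell_policy=self.zero_cell_policy, universe=self.universe
        )

    def sim_params(self) -> SimParams:
        return SimParams(depth=self.sim_depth)


# -- input loading ----------------------------------------------------------


def _read_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_sources(input_dir: str | Path) -> tuple[list[SourceEvidence], dict]:
    """Read MeSH-keyed evidence plus any foreign-keyed evidence, mapping the
    latter through ``mapping.tsv``; returns the sources and mapping stats."""
    input_dir = Path(input_dir)
    sources: list[SourceEvidence] = []
    reports: dict[str, dict] = {}
    evidence = _read_tsv(input_dir / "evidence.tsv")
    for source_id, group in evidence.groupby("source_id", sort=True):
        source_type = group["source_type"].iloc[0]
        rows = [
            (row.gene_symbol, row.mesh_ui, row.directionality or "unknown")
            for row in group.itertuples(index=False)
        ]
        identity = {ui: {ui} for _, ui, _ in rows}
        source, report = map_to_mesh(str(source_id), source_type, rows, identity)
        sources.append(source)
        reports[str(source_id)] = dataclasses.asdict(report)
    raw_path = input_dir / "raw_evidence.tsv"
    if raw_path.exists():
        raw = _read_tsv(raw_path)
        mapping_frame = _read_tsv(input_dir / "mapping.tsv")
        mapping: dict[str, set[str]] = {}
        for row in mapping_frame.itertuples(index=False):
            mapping.setdefault(row.foreign_id, set()).add(row.mesh_ui)
        for source_id, group in raw.groupby("source_id", sort=True):
            source_type = group["source_type"].iloc[0]
            rows = [
                (row.gene_symbol, row.foreign_id, row.directionality or "unknown")
                for row in group.itertuples(index=False)
            ]
            source, report = map_to_mesh(str(source_id), source_type, rows, mapping)
            sources.append(source)
            reports[str(source_id)] = dataclasses.asdict(report)
    sources.sort(key=lambda s: s.source_id)
    return sources, reports


def load_known_indications(input_dir: str | Path) -> set[tuple[str, str]]:
    frame = _read_tsv(Path(input_dir) / "indications_known.tsv")
    return {(row.drug_id, row.mesh_ui) for row in frame.itertuples(index=False)}


# -- stages -----------------------------------------------------------------


@dataclass(frozen=True)
class RankResult:
    sources: tuple[SourceEvidence, ...]
    gold: GoldSelection
    lls_by_source: dict[str, float]
    scored: tuple[ScoredAssociation, ...]
    d_used: float
    auc_by_d: dict[float, float] = field(default_factory=dict)
    mapping_reports: dict = field(default_factory=dict)


def stage_rank(input_dir: str | Path, config: PipelineConfig = PipelineConfig()) -> RankResult:
    sources, reports = load_sources(input_dir)
    gold = select_gold_standard(sources, config.ranking_config())
    d_used = config.d
    auc_by_d: dict[float, float] = {}
    if config.tune_d:
        tuned = tune_D(sources, gold.source_id, config=config.ranking_config())
        d_used = tuned.best_D
        auc_by_d = dict(tuned.auc_by_D)
    ranking = RankingConfig(
        D=d_used, zero_cell_policy=config.zero_cell_policy, universe=config.universe
    )
    lls = per_source_lls(sources, gold.source_id, ranking)
    scored = score_all(sources, gold.source_id, ranking)
    return RankResult(
        tuple(sources), gold, lls, tuple(scored), d_used, auc_by_d, reports
    )


def build_graph(
    input_dir: str | Path, scored: Sequence[ScoredAssociation]
) -> SemanticGraph:
    """Assemble the integrated graph from the fixture tables plus the scored
    associations, merge rare-disease MeSH synonyms and drop unconnected
    nodes."""
    input_dir = Path(input_dir)
    graph = SemanticGraph()
    mesh = _read_tsv(input_dir / "mesh.tsv")
    for row in mesh.itertuples(index=False):
        graph.add_node(
            row.mesh_ui,
            COMMON_DISEASE,
            {"mesh_ui": row.mesh_ui, "heading": row.heading, "tree_numbers": row.tree_numbers},
        )
    rare_path = input_dir / "rare_diseases.tsv"
    rare_parents: list[tuple[str, str]] = []
    if rare_path.exists():
        for row in _read_tsv(rare_path).itertuples(index=False):
            attrs = {"ordo_id": row.ordo_id, "name": row.name}
            if row.mesh_ui:
                attrs["mesh_ui"] = row.mesh_ui
            graph.add_node(row.ordo_id, RARE_DISEASE, attrs)
            if row.parent_ordo:
                rare_parents.append((row.ordo_id, row.parent_ordo))
    for child, parent in rare_parents:
        graph.add_edge(child, parent, "has_parent")
    for row in _read_tsv(input_dir / "drugs.tsv").itertuples(index=False):
        graph.add_node(
            row.drug_id,
            SMALL_MOLECULE,
            {"name": row.name, "group": row.group, "category": row.category},
        )
    proteins = _read_tsv(input_dir / "proteins.tsv")
    genes = sorted(
        set(proteins["gene_symbol"]) | {assoc.gene for assoc in scored}
    )
    for gene in genes:
        graph.add_node(gene, GENE, {"symbol": gene})
    for row in proteins.itertuples(index=False):
        graph.add_node(row.protein_id, PROTEIN, {"name": row.protein_id})
        graph.add_edge(row.protein_id, row.gene_symbol, "encoded_by")
    for row in _read_tsv(input_dir / "targets.tsv").itertuples(index=False):
        attrs = {}
        if row.action:
            attrs["action"] = row.action
        if row.activity_type:
            attrs["activity_type"] = row.activity_type
        if row.activity_nm:
            attrs["activity_nm"] = row.activity_nm
        graph.add_edge(row.drug_id, row.protein_id, "binds_to", attrs)
    n_skipped = 0
    for assoc in scored:
        if not graph.has_node(assoc.disease):
            n_skipped += 1
            continue
        graph.add_edge(
            assoc.gene,
            assoc.disease,
            "involved_in",
            {
                "association_score": f"{assoc.association_score:.10g}",
                "ws": f"{assoc.ws:.10g}",
                "n_sources": str(assoc.n_sources),
                "directionality": assoc.directionality,
            },
        )
    if n_skipped:
        log.warning("%d scored association(s) reference unknown diseases", n_skipped)
    for row in _read_tsv(input_dir / "indications_known.tsv").itertuples(index=False):
        if graph.has_node(row.drug_id) and graph.has_node(row.mesh_ui):
            graph.add_edge(row.drug_id, row.mesh_ui, "has_indication", {"source": row.source})
        else:
            log.warning("known indication %s->%s skipped (unknown endpoint)", row.drug_id, row.mesh_ui)
    for row in _read_tsv(input_dir / "side_effects.tsv").itertuples(index=False):
        if graph.has_node(row.drug_id) and graph.has_node(row.mesh_ui):
            graph.add_edge(row.drug_id, row.mesh_ui, "has_side_effect")
        else:
            log.warning("side effect %s->%s skipped (unknown endpoint)", row.drug_id, row.mesh_ui)
    graph = merge_rare_disease_synonyms(graph)
    dropped = graph.remove_isolated()
    log.info("build: removed %d unconnected node(s)", dropped)
    graph.validate()
    return graph


def filter_config(input_dir: str | Path, config: PipelineConfig) -> FilterConfig:
    input_dir = Path(input_dir)
    inhibitory, activating = load_action_sets(input_dir / "actions.yaml")
    adme = load_adme_genes(input_dir / "adme_genes.txt")
    return FilterConfig(
        equivalence_threshold=config.equivalence_threshold,
        inhibitory_actions=inhibitory,
        activating_actions=activating,
        adme_genes=adme,
        sim_params=config.sim_params(),
    )


# -- writers ----------------------------------------------------------------


def _write_scored(path: Path, scored: Sequence[ScoredAssociation]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\tmesh_ui\tws\tassociation_score\tn_sources\tdirectionality\n")
        for assoc in scored:
            handle.write(
                f"{assoc.gene}\t{assoc.disease}\t{assoc.ws:.6f}\t"
                f"{assoc.association_score:.6f}\t{assoc.n_sources}\t{assoc.directionality}\n"
            )


def _write_areas(path: Path, areas: Sequence[AreaScore]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("ta\tn_diseases\tp_gd\tp_drd\ttau\trta\teligible\n")
        for area in areas:
            handle.write(
                f"{area.ta}\t{area.n_diseases}\t{area.p_gd:.6f}\t{area.p_drd:.6f}\t"
                f"{area.tau:.6f}\t{area.rta:.6f}\t{str(area.eligible).lower()}\n"
            )


def _write_mappings(path: Path, mappings: Sequence[SubgraphMapping]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "drug\tprotein\tgene\tdisease\traw_activity_nm\tnorm_activity\t"
            "association_score\tmapping_score\n"
        )
        for m in mappings:
            raw = "" if m.raw_activity_nm is None else f"{m.raw_activity_nm:.6g}"
            handle.write(
                f"{m.drug}\t{m.protein}\t{m.gene}\t{m.disease}\t{raw}\t"
                f"{m.norm_activity:.6f}\t{m.association_score:.6f}\t{m.mapping_score:.6f}\n"
            )


def _write_indications(path: Path, indications: Sequence[InferredIndication]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("drug\tdisease\tscore\tvia_protein\tvia_gene\n")
        for ind in indications:
            handle.write(
                f"{ind.drug}\t{ind.disease}\t{ind.score:.6f}\t"
                f"{ind.best_mapping.protein}\t{ind.best_mapping.gene}\n"
            )


# -- orchestration ----------------------------------------------------------


def run_all(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Execute every stage, write all intermediates and the run manifest."""
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def timed(stage: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except (PipelineError,) as exc:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(stage, f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        log.info("stage %-8s %.2fs", stage, time.perf_counter() - start)
        return result

    rank = timed("rank", lambda: stage_rank(input_dir, config))
    _write_scored(out_dir / "scored_associations.tsv", rank.scored)
    manifest["stages"]["rank"] = {
        "gold_source": rank.gold.source_id,
        "average_ranks": dict(sorted(rank.gold.average_ranks.items())),
        "lls_by_source": dict(sorted(rank.lls_by_source.items())),
        "d_used": rank.d_used,
        "auc_by_d": {f"{d:g}": auc for d, auc in sorted(rank.auc_by_d.items())},
        "n_scored": len(rank.scored),
        "mapping_reports": rank.mapping_reports,
    }

    graph = timed("build", lambda: build_graph(input_dir, rank.scored))
    save_graph(graph, out_dir / "nodes.tsv", out_dir / "edges.tsv")
    manifest["stages"]["build"] = {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges}

    areas = timed(
        "areas",
        lambda: score_areas(graph, config.size_factor_mode, config.n_areas_reference),
    )
    _write_areas(out_dir / "areas.tsv", areas)
    manifest["stages"]["areas"] = {
        "n_areas": len(areas),
        "top_tau": areas[0].ta if areas else None,
    }

    tree = timed("mine", lambda: MeshTree.from_tsv(input_dir / "mesh.tsv"))
    candidates = candidate_drugs(graph)
    mappings = timed("mine", lambda: find_mappings(graph, candidates))
    _write_mappings(out_dir / "mappings.tsv", mappings)
    manifest["stages"]["mine"] = {
        "n_candidates": len(candidates),
        "n_mappings": len(mappings),
    }

    fconfig = filter_config(input_dir, config)
    cascade: CascadeResult = timed(
        "filter", lambda: run_cascade(mappings, graph, tree, fconfig)
    )
    _write_mappings(out_dir / "kept_mappings.tsv", cascade.kept)
    manifest["stages"]["filter"] = {
        "sequential_counts": dict(cascade.sequential_counts),
        "independent_counts": dict(cascade.independent_counts),
        "n_kept": len(cascade.kept),
    }

    indications = timed("validate", lambda: dedupe(cascade.kept))
    _write_indications(out_dir / "indications_inferred.tsv", indications)
    known = load_known_indications(input_dir)
    report: ValidationReport = timed(
        "validate",
        lambda: evaluate(
            indications, known, graph, tree, config.validation_sim, config.sim_params()
        ),
    )
    manifest["stages"]["validate"] = {
        "n_indications": len(indications),
        **dataclasses.asdict(report),
    }

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest
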