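"""Deterministic toy-scale fixture generator with planted structure.

The generator emits every input table the pipeline consumes — per-source
gene--disease evidence (one source keyed by MIM ids plus its identifier
mapping table, the rest keyed by MeSH), a MeSH disease forest, drug /
target / indication / side-effect tables, a rare-disease table with MeSH
synonyms, an ADME gene list and an action-term table — together with a
``truth.json`` manifest listing everything that was planted, so every
pipeline stage can be tested end-to-end without any download.

Planted structure:

* a gold standard of true gene--disease pairs, sampled into each source
  with a per-source reliability (and diluted with noise pairs), so source
  ranking is recoverable;
* full drug -> protein -> gene -> disease support chains for a handful of
  repositioning opportunities that must survive the filter cascade;
* side-effect traps: chains whose inferred disease sits at a chosen node
  distance from a recorded side effect of the same drug (removed by the
  cascade iff the distance is within the equivalence threshold);
* one mechanism contradiction (inhibitory drug on a LoF association) and
  one chain through an ADME gene;
* known indications planted at chosen node distances from inferred
  diseases, giving the validation recall curve exact step positions.

A single integer seed drives one :class:`numpy.random.Generator` stream;
the same spec always produces byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .filters import (
    DEFAULT_ACTIVATING_ACTIONS,
    DEFAULT_INHIBITORY_ACTIONS,
    save_action_sets,
)
from .mesh_sim import MeshTree, node_distance

log = logging.getLogger(__name__)

Pair = tuple[str, str]


class FixtureError(ValueError):
    """The requested fixture is unrealizable."""


@dataclass(frozen=True)
class SourceSpec:
    """One evidence source: reliability is the probability that a gold pair
    is included; noise_rate sizes the non-gold dilution relative to the
    gold standard."""

    source_id: str
    source_type: str
    reliability: float
    noise_rate: float = 0.3


DEFAULT_SOURCES = (
    SourceSpec("src_curated", "curated", 0.9, 0.3),
    SourceSpec("src_literature", "literature", 0.6, 0.3),
    SourceSpec("src_predicted", "predicted", 0.3, 0.3),
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    # MeSH forest shape
    n_areas: int = 3
    branching: int = 2
    mesh_depth: int = 5
    multi_area_fraction: float = 0.05
    # evidence layer
    n_genes: int = 120
    n_gold: int = 200
    sources: tuple[SourceSpec, ...] = DEFAULT_SOURCES
    directionality_rate: float = 0.2
    # drug layer
    n_drugs: int = 30
    targets_per_drug: int = 2
    fraction_approved: float = 0.8
    missing_activity_rate: float = 0.2
    n_known_indications: int = 12
    n_side_effects: int = 15
    # rare diseases
    n_rare_diseases: int = 3
    n_rare_synonyms: int = 2
    # planted structure
    planted_indications: int = 5
    trap_dists: tuple[int, ...] = (1, 2, 3)
    planted_contradictions: int = 1
    planted_adme_hits: int = 1
    known_dists: tuple[int, ...] = (1, 2, 3, 10)

    def __post_init__(self) -> None:
        if self.mesh_depth < 1 or self.mesh_depth > 10:
            raise FixtureError("mesh_depth must be in 1..10")
        if self.branching < 1 or self.n_areas < 1:
            raise FixtureError("branching and n_areas must be >= 1")
        for name in (
            "n_genes", "n_gold", "n_drugs", "targets_per_drug",
            "n_known_indications", "n_side_effects", "n_rare_diseases",
            "n_rare_synonyms", "planted_indications",
            "planted_contradictions", "planted_adme_hits",
        ):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        for name in ("multi_area_fraction", "directionality_rate",
                     "fraction_approved", "missing_activity_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1]")
        if self.n_rare_synonyms > self.n_rare_diseases:
            raise FixtureError("n_rare_synonyms cannot exceed n_rare_diseases")
        if not self.sources:
            raise FixtureError("at least one source is required")
        for dist in self.trap_dists + self.known_dists:
            if dist < 1 or dist - 1 > 2 * self.mesh_depth:
                raise FixtureError(
                    f"node distance {dist} is unrealizable at mesh_depth {self.mesh_depth}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "sources" in data:
            data["sources"] = tuple(SourceSpec(**item) for item in data["sources"])
        for key in ("trap_dists", "known_dists"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sources"] = [dataclasses.asdict(s) for s in self.sources]
        data["trap_dists"] = list(self.trap_dists)
        data["known_dists"] = list(self.known_dists)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


# -- mesh forest ------------------------------------------------------------


def build_mesh(spec: FixtureSpec, rng: np.random.Generator) -> MeshTree:
    """Labeled complete k-ary trees, one per top-level area; every position
    (including the area root) carries a disease.  A fraction of diseases
    gains a second tree number in another area."""
    entries: dict[str, tuple[str, list[str]]] = {}
    positions_by_area: list[list[str]] = []
    ui_counter = 0
    for area_index in range(1, spec.n_areas + 1):
        area = f"C{area_index:02d}"
        level = [area]
        area_positions = [area]
        for _ in range(spec.mesh_depth):
            level = [
                f"{parent}.{child + 1:03d}"
                for parent in level
                for child in range(spec.branching)
            ]
            area_positions.extend(level)
        positions_by_area.append(area_positions)
        for position in area_positions:
            ui_counter += 1
            ui = f"D{ui_counter:06d}"
            entries[ui] = (f"Disease {ui}", [position])
    uis = sorted(entries)
    n_multi = round(spec.multi_area_fraction * len(uis))
    if spec.n_areas > 1 and n_multi:
        chosen = rng.choice(len(uis), size=n_multi, replace=False)
        for index in sorted(chosen):
            ui = uis[index]
            primary_area = int(entries[ui][1][0].split(".")[0][1:]) - 1
            other_areas = [a for a in range(spec.n_areas) if a != primary_area]
            area = other_areas[int(rng.integers(len(other_areas)))]
            position = positions_by_area[area][
                int(rng.integers(len(positions_by_area[area])))
            ]
            if position not in entries[ui][1]:
                entries[ui][1].append(position)
    return MeshTree({ui: (h, tuple(ns)) for ui, (h, ns) in entries.items()})


def _pair_at_distance(
    tree: MeshTree, dist: int, used: set[str]
) -> tuple[str, str]:
    """First (in sorted UI order) unused pair at exactly ``dist`` nodes."""
    uis = tree.uis()
    for a in uis:
        if a in used:
            continue
        if dist == 1:
            return a, a
        for b in uis:
            if b in used or b == a:
                continue
            if node_distance(tree, a, b) == dist:
                return a, b
    raise FixtureError(f"no unused disease pair at node distance {dist}")


# -- evidence layer ---------------------------------------------------------


def sample_evidence(
    spec: FixtureSpec,
    rng: np.random.Generator,
    genes: Sequence[str],
    diseases: Sequence[str],
) -> tuple[list[Pair], dict[Pair, str], dict[str, list[Pair]]]:
    """Sample the gold standard and each source's pair list.

    Returns (gold pairs, directionality per gold pair, pairs per source).
    Source pairs = gold pairs kept with probability ``reliability`` plus
    ``round(noise_rate * n_gold)`` random non-gold pairs.
    """
    n_cells = len(genes) * len(diseases)
    if spec.n_gold > n_cells:
        raise FixtureError("n_gold exceeds the gene x disease space")
    max_noise = max(round(s.noise_rate * spec.n_gold) for s in spec.sources)
    if max_noise > n_cells - spec.n_gold:
        raise FixtureError("noise pairs exceed the non-gold gene x disease space")
    gold_index = rng.choice(n_cells, size=spec.n_gold, replace=False)
    gold_cells = set(int(i) for i in gold_index)

    def cell_pair(cell: int) -> Pair:
        return genes[cell // len(diseases)], diseases[cell % len(diseases)]

    gold = [cell_pair(cell) for cell in sorted(gold_cells)]
    directionality: dict[Pair, str] = {}
    for pair in gold:
        if rng.random() < spec.directionality_rate:
            directionality[pair] = "LoF" if rng.random() < 0.5 else "GoF"
        else:
            directionality[pair] = "unknown"
    by_source: dict[str, list[Pair]] = {}
    for source in spec.sources:
        keep = rng.random(len(gold)) < source.reliability
        pairs = [pair for pair, kept in zip(gold, keep) if kept]
        n_noise = round(source.noise_rate * spec.n_gold)
        chosen: set[int] = set()
        while len(chosen) < n_noise:
            cell = int(rng.integers(n_cells))
            if cell not in gold_cells and cell not in chosen:
                chosen.add(cell)
        pairs.extend(cell_pair(cell) for cell in sorted(chosen))
        by_source[source.source_id] = pairs
    return gold, directionality, by_source


# -- full bundle ------------------------------------------------------------


@dataclass(frozen=True)
class PlantedChain:
    kind: str
    drug: str
    protein: str
    gene: str
    disease_ui: str
    action: str = ""
    directionality: str = "unknown"
    companion_ui: str = ""  # trap: side-effect disease; known: the known disease
    dist: int = 0


def _plant_chains(spec: FixtureSpec, tree: MeshTree, rng: np.random.Generator) -> list[PlantedChain]:
    used: set[str] = set()
    chains: list[PlantedChain] = []
    counter = 0

    def next_ids(kind: str) -> tuple[str, str, str]:
        nonlocal counter
        counter += 1
        return f"PDRG{counter:03d}", f"PPRT{counter:03d}", f"PGEN{counter:03d}"

    leaves = [ui for ui in tree.uis() if all(
        n.count(".") == spec.mesh_depth for n in tree.tree_numbers(ui)[:1]
    )]
    free_leaves = [ui for ui in leaves]

    def take_leaf() -> str:
        for ui in free_leaves:
            if ui not in used:
                used.add(ui)
                return ui
        raise FixtureError("not enough free diseases for planted chains")

    for _ in range(spec.planted_indications):
        drug, protein, gene = next_ids("indication")
        chains.append(PlantedChain("indication", drug, protein, gene, take_leaf()))
    for dist in spec.trap_dists:
        drug, protein, gene = next_ids("trap")
        target, side_effect = _pair_at_distance(tree, dist, used)
        used.update({target, side_effect})
        chains.append(
            PlantedChain("trap", drug, protein, gene, target,
                         companion_ui=side_effect, dist=dist)
        )
    for _ in range(spec.planted_contradictions):
        drug, protein, gene = next_ids("contradiction")
        chains.append(
            PlantedChain("contradiction", drug, protein, gene, take_leaf(),
                         action="inhibitor", directionality="LoF")
        )
    for index in range(spec.planted_adme_hits):
        drug, protein, _ = next_ids("adme")
        chains.append(
            PlantedChain("adme", drug, protein, f"PADME{index + 1:03d}", take_leaf())
        )
    for dist in spec.known_dists:
        drug, protein, gene = next_ids("known")
        inferred, known = _pair_at_distance(tree, dist, used)
        used.update({inferred, known})
        chains.append(
            PlantedChain("known", drug, protein, gene, inferred,
                         companion_ui=known, dist=dist)
        )
    return chains


def generate(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the full fixture bundle; returns the truth manifest.

    All content is assembled in memory first, so an unrealizable spec
    raises before any file is written.  Same spec, same bytes.
    """
    rng = np.random.default_rng(spec.seed)
    tree = build_mesh(spec, rng)
    diseases = tree.uis()
    genes = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    gold, directionality, by_source = sample_evidence(spec, rng, genes, diseases)
    chains = _plant_chains(spec, tree, rng)

    # planted pairs join the gold standard and the two most reliable sources
    ranked_sources = sorted(spec.sources, key=lambda s: -s.reliability)
    support_sources = [s.source_id for s in ranked_sources[: min(2, len(ranked_sources))]]
    for chain in chains:
        pair = (chain.gene, chain.disease_ui)
        gold.append(pair)
        directionality[pair] = chain.directionality
        for source_id in support_sources:
            by_source[source_id].append(pair)

    # MIM identifiers + mapping for the most reliable source
    mim_source = ranked_sources[0].source_id
    mim_ids = {ui: f"{100000 + i}" for i, ui in enumerate(diseases)}

    # drug layer -----------------------------------------------------------
    drug_rows: list[tuple[str, str, str, str]] = []  # id, name, group, category
    target_rows: list[tuple[str, str, str, str, str]] = []  # drug, protein, action, type, nM
    protein_rows: dict[str, str] = {}  # protein -> gene symbol
    recognized_actions = sorted(DEFAULT_INHIBITORY_ACTIONS | DEFAULT_ACTIVATING_ACTIONS)
    for i in range(spec.n_drugs):
        drug = f"DRUG{i + 1:03d}"
        approved = i == 0 or rng.random() < spec.fraction_approved
        group = "approved" if approved else "experimental"
        if approved and rng.random() < 0.2:
            group = "approved|investigational"
        drug_rows.append((drug, f"compound-{i + 1}", group, "synthetic"))
        for _ in range(spec.targets_per_drug):
            gene = genes[int(rng.integers(len(genes)))]
            protein = f"PROT_{gene}"
            protein_rows[protein] = gene
            if rng.random() < spec.missing_activity_rate:
                action = recognized_actions[int(rng.integers(len(recognized_actions)))]
                target_rows.append((drug, protein, action, "", ""))
            else:
                value = 10.0 ** float(rng.uniform(0.0, 6.0))
                action = ""
                if rng.random() < 0.5:
                    action = recognized_actions[int(rng.integers(len(recognized_actions)))]
                target_rows.append((drug, protein, action, "IC50", f"{value:.6g}"))
    for chain in chains:
        drug_rows.append((chain.drug, f"compound-{chain.drug}", "approved", "synthetic"))
        protein_rows[chain.protein] = chain.gene
        target_rows.append((chain.drug, chain.protein, chain.action, "IC50", "1"))

    # known indications / side effects -------------------------------------
    approved_random = [row[0] for row in drug_rows if "approved" in row[2] and row[0].startswith("DRUG")]
    indication_rows: list[tuple[str, str, str]] = []
    for _ in range(spec.n_known_indications):
        drug = approved_random[int(rng.integers(len(approved_random)))]
        disease = diseases[int(rng.integers(len(diseases)))]
        indication_rows.append((drug, disease, "fixture"))
    side_effect_rows: list[tuple[str, str]] = []
    for _ in range(spec.n_side_effects):
        drug = f"DRUG{int(rng.integers(spec.n_drugs)) + 1:03d}"
        disease = diseases[int(rng.integers(len(diseases)))]
        side_effect_rows.append((drug, disease))
    for chain in chains:
        if chain.kind == "trap":
            side_effect_rows.append((chain.drug, chain.companion_ui))
        elif chain.kind == "known":
            indication_rows.append((chain.drug, chain.companion_ui, "fixture"))

    # rare diseases ---------------------------------------------------------
    rare_rows: list[tuple[str, str, str, str]] = []  # ordo, name, mesh_ui, parent
    rare_synonyms: list[dict[str, str]] = []
    synonym_uis: list[str] = []
    indication_chains = [c for c in chains if c.kind == "indication"]
    for index in range(spec.n_rare_diseases):
        ordo = f"ORDO:{index + 1:06d}"
        mesh_ui = ""
        if index < spec.n_rare_synonyms:
            if index == 0 and indication_chains:
                mesh_ui = indication_chains[0].disease_ui
            else:
                candidates = [
                    ui for ui in diseases
                    if ui not in synonym_uis
                    and all(ui != c.disease_ui and ui != c.companion_ui for c in chains)
                ]
                mesh_ui = candidates[int(rng.integers(len(candidates)))]
            synonym_uis.append(mesh_ui)
            rare_synonyms.append({"ordo_id": ordo, "mesh_ui": mesh_ui})
        parent = "" if index == 0 else "ORDO:000001"
        rare_rows.append((ordo, f"rare-disease-{index + 1}", mesh_ui, parent))
    rare_by_ui = {entry["mesh_ui"]: entry["ordo_id"] for entry in rare_synonyms}

    # ADME list -------------------------------------------------------------
    adme_symbols = sorted({c.gene for c in chains if c.kind == "adme"})
    planted_genes = {c.gene for c in chains}
    extra_candidates = [g for g in genes if g not in planted_genes]
    extra = rng.choice(len(extra_candidates), size=min(3, len(extra_candidates)), replace=False)
    adme_symbols.extend(sorted(extra_candidates[int(i)] for i in extra))

    # write bundle ----------------------------------------------------------
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree.to_tsv(outdir / "mesh.tsv")

    source_types = {s.source_id: s.source_type for s in spec.sources}
    with open(outdir / "evidence.tsv", "w", encoding="utf-8") as handle:
        handle.write("source_id\tsource_type\tgene_symbol\tmesh_ui\tdirectionality\n")
        for source_id in sorted(by_source):
            if source_id == mim_source:
                continue
            for gene, ui in sorted(set(by_source[source_id])):
                dirn = directionality.get((gene, ui), "unknown")
                handle.write(f"{source_id}\t{source_types[source_id]}\t{gene}\t{ui}\t{dirn}\n")
    with open(outdir / "raw_evidence.tsv", "w", encoding="utf-8") as handle:
        handle.write("source_id\tsource_type\tgene_symbol\tforeign_namespace\tforeign_id\tdirectionality\n")
        for gene, ui in sorted(set(by_source[mim_source])):
            dirn = directionality.get((gene, ui), "unknown")
            handle.write(
                f"{mim_source}\t{source_types[mim_source]}\t{gene}\tMIM\t{mim_ids[ui]}\t{dirn}\n"
            )
    with open(outdir / "mapping.tsv", "w", encoding="utf-8") as handle:
        handle.write("foreign_namespace\tforeign_id\tmesh_ui\n")
        for ui in diseases:
            handle.write(f"MIM\t{mim_ids[ui]}\t{ui}\n")
    with open(outdir / "drugs.tsv", "w", encoding="utf-8") as handle:
        handle.write("drug_id\tname\tgroup\tcategory\n")
        for row in sorted(drug_rows):
            handle.write("\t".join(row) + "\n")
    with open(outdir / "proteins.tsv", "w", encoding="utf-8") as handle:
        handle.write("protein_id\tgene_symbol\n")
        for protein in sorted(protein_rows):
            handle.write(f"{protein}\t{protein_rows[protein]}\n")
    with open(outdir / "targets.tsv", "w", encoding="utf-8") as handle:
        handle.write("drug_id\tprotein_id\taction\tactivity_type\tactivity_nm\n")
        for row in sorted(target_rows):
            handle.write("\t".join(row) + "\n")
    with open(outdir / "indications_known.tsv", "w", encoding="utf-8") as handle:
        handle.write("drug_id\tmesh_ui\tsource\n")
        for row in sorted(set(indication_rows)):
            handle.write("\t".join(row) + "\n")
    with open(outdir / "side_effects.tsv", "w", encoding="utf-8") as handle:
        handle.write("drug_id\tmesh_ui\n")
        for row in sorted(set(side_effect_rows)):
            handle.write("\t".join(row) + "\n")
    with open(outdir / "rare_diseases.tsv", "w", encoding="utf-8") as handle:
        handle.write("ordo_id\tname\tmesh_ui\tparent_ordo\n")
        for row in rare_rows:
            handle.write("\t".join(row) + "\n")
    with open(outdir / "adme_genes.txt", "w", encoding="utf-8") as handle:
        for symbol in adme_symbols:
            handle.write(symbol + "\n")
    save_action_sets(outdir / "actions.yaml")
    spec.to_yaml(outdir / "fixture_spec.yaml")

    def final_disease_node(ui: str) -> str:
        return rare_by_ui.get(ui, ui)

    truth = {
        "spec": json.loads(json.dumps(dataclasses.asdict(spec))),
        "gold": [list(pair) for pair in sorted(set(gold))],
        "sources": {
            source_id: {
                "pairs": [list(pair) for pair in sorted(set(pairs))],
                "n_gold_members": len(set(pairs) & set(gold)),
            }
            for source_id, pairs in by_source.items()
        },
        "planted_indications": [
            {
                "drug": c.drug, "protein": c.protein, "gene": c.gene,
                "disease_ui": c.disease_ui,
                "disease_node": final_disease_node(c.disease_ui),
            }
            for c in chains if c.kind == "indication"
        ],
        "traps": [
            {
                "drug": c.drug, "gene": c.gene, "disease_ui": c.disease_ui,
                "side_effect_ui": c.companion_ui, "dist": c.dist,
                "disease_node": final_disease_node(c.disease_ui),
            }
            for c in chains if c.kind == "trap"
        ],
        "contradictions": [
            {"drug": c.drug, "gene": c.gene, "disease_ui": c.disease_ui,
             "disease_node": final_disease_node(c.disease_ui)}
            for c in chains if c.kind == "contradiction"
        ],
        "adme_hits": [
            {"drug": c.drug, "gene": c.gene, "disease_ui": c.disease_ui,
             "disease_node": final_disease_node(c.disease_ui)}
            for c in chains if c.kind == "adme"
        ],
        "knowns_at_dist": [
            {"drug": c.drug, "inferred_ui": c.disease_ui,
             "known_ui": c.companion_ui, "dist": c.dist,
             "inferred_node": final_disease_node(c.disease_ui)}
            for c in chains if c.kind == "known"
        ],
        "rare_synonyms": rare_synonyms,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return truth


def shape_report(bundle_dir: str | Path) -> dict:
    """Summary statistics of a generated bundle: per-source pair counts,
    the pairwise overlap matrix and per-area disease counts."""
    bundle_dir = Path(bundle_dir)
    frames = []
    evidence = pd.read_csv(bundle_dir / "evidence.tsv", sep="\t", dtype=str)
    frames.append(evidence[["source_id", "gene_symbol", "mesh_ui"]])
    raw_path = bundle_dir / "raw_evidence.tsv"
    if raw_path.exists():
        raw = pd.read_csv(raw_path, sep="\t", dtype=str)
        mapping = pd.read_csv(bundle_dir / "mapping.tsv", sep="\t", dtype=str)
        merged = raw.merge(mapping, on=["foreign_namespace", "foreign_id"])
        frames.append(merged[["source_id", "gene_symbol", "mesh_ui"]])
    table = pd.concat(frames, ignore_index=True).drop_duplicates()
    pair_sets = {
        source_id: set(map(tuple, group[["gene_symbol", "mesh_ui"]].values))
        for source_id, group in table.groupby("source_id")
    }
    source_ids = sorted(pair_sets)
    overlap = {
        a: {
            b: (100.0 * len(pair_sets[a] & pair_sets[b]) / len(pair_sets[a]) if pair_sets[a] else 0.0)
            for b in source_ids
        }
        for a in source_ids
    }
    mesh = pd.read_csv(bundle_dir / "mesh.tsv", sep="\t", dtype=str)
    area_counts: dict[str, int] = {}
    for numbers in mesh["tree_numbers"]:
        for area in {n.split(".")[0] for n in str(numbers).split("|") if n}:
            area_counts[area] = area_counts.get(area, 0) + 1
    return {
        "pair_counts": {sid: len(pair_sets[sid]) for sid in source_ids},
        "overlap_percent": overlap,
        "area_disease_counts": dict(sorted(area_counts.items())),
    }
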