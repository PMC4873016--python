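"""The three-stage pruning cascade applied to mined mappings.

1. *Side-effect similarity*: a mapping is dismissed when its drug already
   has a recorded side effect on the inferred disease or on any disease
   semantically equivalent to it (Sim >= the equivalence threshold ET,
   default 0.768 = one node away in the MeSH hierarchy).
2. *Mechanism contradiction*: a mapping is dismissed when the drug's action
   on its target contradicts the gene--disease directionality (an
   inhibitory drug against a loss-of-function association, or an activating
   drug against a gain-of-function association).
3. *ADME genes*: mappings routed through absorption / distribution /
   metabolism / excretion genes are pharmacokinetic artifacts and dismissed.

Each filter is contractive and idempotent, and each predicate depends only
on the mapping itself, so the final kept set is invariant to stage order;
the per-stage removal counts are order-dependent and are reported under
both sequential and independent accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .graph_model import (
    ACTION_ATTR,
    DIRECTIONALITY_ATTR,
    HAS_SIDE_EFFECT,
    MESH_UI_ATTR,
    SemanticGraph,
)
from .mesh_sim import MeshTree, SimParams, sim
from .mining import SubgraphMapping

log = logging.getLogger(__name__)

STAGE_SIDE_EFFECT = "side_effect"
STAGE_DIRECTIONALITY = "directionality"
STAGE_ADME = "adme"
DEFAULT_STAGE_ORDER = (STAGE_SIDE_EFFECT, STAGE_DIRECTIONALITY, STAGE_ADME)

DEFAULT_INHIBITORY_ACTIONS = frozenset(
    {
        "antagonist",
        "inhibitor",
        "blocker",
        "negative allosteric modulator",
        "inverse agonist",
    }
)
DEFAULT_ACTIVATING_ACTIONS = frozenset(
    {
        "agonist",
        "activator",
        "positive allosteric modulator",
        "partial agonist",
        "opener",
        "inducer",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    equivalence_threshold: float = 0.768
    inhibitory_actions: frozenset[str] = DEFAULT_INHIBITORY_ACTIONS
    activating_actions: frozenset[str] = DEFAULT_ACTIVATING_ACTIONS
    adme_genes: frozenset[str] = frozenset()
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    sim_params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        # values just above 1 are a legal sentinel meaning "exact matches only"
        if not 0.0 <= self.equivalence_threshold <= 1.5:
            raise ValueError("equivalence threshold out of range")
        if self.inhibitory_actions & self.activating_actions:
            raise ValueError("inhibitory and activating action sets must be disjoint")
        unknown = set(self.stage_order) - set(DEFAULT_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown cascade stage(s): {sorted(unknown)}")


def load_action_sets(path: str | Path) -> tuple[frozenset[str], frozenset[str]]:
    """Read ``actions.yaml``: the editable inhibitory/activating term table."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    return (
        frozenset(str(t).lower() for t in data.get("inhibitory", [])),
        frozenset(str(t).lower() for t in data.get("activating", [])),
    )


def save_action_sets(
    path: str | Path,
    inhibitory: frozenset[str] = DEFAULT_INHIBITORY_ACTIONS,
    activating: frozenset[str] = DEFAULT_ACTIVATING_ACTIONS,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            {"inhibitory": sorted(inhibitory), "activating": sorted(activating)},
            handle,
            sort_keys=True,
        )


def load_adme_genes(path: str | Path) -> frozenset[str]:
    """Read ``adme_genes.txt``: one gene symbol per line (case-insensitive)."""
    with open(path, "r", encoding="utf-8") as handle:
        return frozenset(
            line.strip().upper() for line in handle if line.strip()
        )


def filter_side_effects(
    mappings: Sequence[SubgraphMapping],
    graph: SemanticGraph,
    tree: MeshTree,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[SubgraphMapping], list[SubgraphMapping]]:
    """Dismiss mappings whose inferred disease is (near-)equal to a known
    side effect of the same drug.

    Equality is exact on the disease node, or semantic with
    Sim >= the equivalence threshold when both diseases resolve to MeSH
    UIs present in the vocabulary; rare diseases without a MeSH UI match
    exactly only.  The drug-wise comparison short-circuits on the first
    hit; the result is independent of iteration order.
    """
    side_effects: dict[str, list[tuple[str, str | None]]] = {}

    def drug_side_effects(drug: str) -> list[tuple[str, str | None]]:
        if drug not in side_effects:
            side_effects[drug] = [
                (rec.target, graph.node(rec.target).attr(MESH_UI_ATTR))
                for rec in graph.out_edges(drug, HAS_SIDE_EFFECT)
            ]
        return side_effects[drug]

    kept: list[SubgraphMapping] = []
    removed: list[SubgraphMapping] = []
    ui_cache: dict[str, str | None] = {}
    for mapping in mappings:
        if mapping.disease not in ui_cache:
            ui_cache[mapping.disease] = graph.node(mapping.disease).attr(MESH_UI_ATTR)
        disease_ui = ui_cache[mapping.disease]
        hit = False
        for se_node, se_ui in drug_side_effects(mapping.drug):
            if se_node == mapping.disease:
                hit = True
                break
            if (
                disease_ui
                and se_ui
                and disease_ui in tree
                and se_ui in tree
                and sim(tree, disease_ui, se_ui, config.sim_params)
                >= config.equivalence_threshold
            ):
                hit = True
                break
        (removed if hit else kept).append(mapping)
    return kept, removed


def filter_directionality(
    mappings: Sequence[SubgraphMapping],
    graph: SemanticGraph,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[SubgraphMapping], list[SubgraphMapping]]:
    """Dismiss mappings whose drug mechanism contradicts the association
    directionality; any missing annotation keeps the mapping."""
    kept: list[SubgraphMapping] = []
    removed: list[SubgraphMapping] = []
    unrecognized: set[str] = set()
    for mapping in mappings:
        action = (graph.edge(mapping.binds_edge).attr(ACTION_ATTR) or "").strip().lower()
        directionality = (
            graph.edge(mapping.involved_edge).attr(DIRECTIONALITY_ATTR) or "unknown"
        )
        contradiction = False
        if action and directionality in ("LoF", "GoF"):
            if action in config.inhibitory_actions:
                contradiction = directionality == "LoF"
            elif action in config.activating_actions:
                contradiction = directionality == "GoF"
            else:
                unrecognized.add(action)
        (removed if contradiction else kept).append(mapping)
    for term in sorted(unrecognized):
        log.warning("unrecognized action term %r; affected mappings kept", term)
    return kept, removed


def filter_adme(
    mappings: Sequence[SubgraphMapping],
    config: FilterConfig = FilterConfig(),
    graph: SemanticGraph | None = None,
) -> tuple[list[SubgraphMapping], list[SubgraphMapping]]:
    """Dismiss mappings routed through an ADME gene (case-insensitive).

    When a graph is supplied the gene node's ``symbol`` attribute is
    matched; otherwise the gene node id is used as the symbol.
    """
    if not config.adme_genes:
        log.warning("ADME gene list is empty; ADME filter is a no-op")
        return list(mappings), []
    kept: list[SubgraphMapping] = []
    removed: list[SubgraphMapping] = []
    for mapping in mappings:
        symbol = mapping.gene
        if graph is not None:
            symbol = graph.node(mapping.gene).attr("symbol") or mapping.gene
        (removed if symbol.upper() in config.adme_genes else kept).append(mapping)
    return kept, removed


@dataclass(frozen=True)
class CascadeResult:
    kept: tuple[SubgraphMapping, ...]
    removed_by_stage: Mapping[str, tuple[SubgraphMapping, ...]]
    #: removals counted on the sequentially shrinking input
    sequential_counts: Mapping[str, int]
    #: removals counted with each filter applied to the original input
    independent_counts: Mapping[str, int]


def run_cascade(
    mappings: Sequence[SubgraphMapping],
    graph: SemanticGraph,
    tree: MeshTree,
    config: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Apply the stages in the configured order, reporting auditable counts."""

    def apply(stage: str, inputs: Sequence[SubgraphMapping]):
        if stage == STAGE_SIDE_EFFECT:
            return filter_side_effects(inputs, graph, tree, config)
        if stage == STAGE_DIRECTIONALITY:
            return filter_directionality(inputs, graph, config)
        if stage == STAGE_ADME:
            return filter_adme(inputs, config, graph)
        raise ValueError(f"unknown cascade stage {stage!r}")

    current: Sequence[SubgraphMapping] = list(mappings)
    removed_by_stage: dict[str, tuple[SubgraphMapping, ...]] = {}
    sequential: dict[str, int] = {}
    independent: dict[str, int] = {}
    for stage in config.stage_order:
        current, removed = apply(stage, current)
        removed_by_stage[stage] = tuple(removed)
        sequential[stage] = len(removed)
        _, removed_alone = apply(stage, mappings)
        independent[stage] = len(removed_alone)
        log.info(
            "cascade stage %s removed %d (sequential) / %d (independent)",
            stage, sequential[stage], independent[stage],
        )
    return CascadeResult(tuple(current), removed_by_stage, sequential, independent)
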