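"""Exhaustive semantic-subgraph mining for indication inference.

The mined pattern is the simplest target-based route from drug to disease:

    drug --binds_to--> protein --encoded_by--> gene --involved_in--> disease

Every concrete match (a *mapping*) of this four-node subgraph over the
candidate drugs (approved small molecules) is enumerated; parallel
``binds_to`` edges yield one mapping each.  A mapping is scored by the mean
of its normalized binding activity and the association score of its
gene--disease edge:

    Score(M) = (norm_activity + association_score) / 2

Binding activities in nM (IC50 / Ki / Kd / Potency) are normalized to
[0, 1] as ``1 - 0.1 * log10(value)``, clamped; edges without a measured
activity (the DrugBank case) receive the fixed normalized value 0.8 so
their mappings are kept without over-weighting unknown activities.
Mappings inferring the same (drug, disease) indication are deduplicated to
the best-scoring one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph_model import (
    ACTIVITY_ATTR,
    ASSOCIATION_SCORE_ATTR,
    BINDS_TO,
    ENCODED_BY,
    INVOLVED_IN,
    SMALL_MOLECULE,
    GraphError,
    SemanticGraph,
)

log = logging.getLogger(__name__)

APPROVED_GROUP = "approved"
MISSING_ACTIVITY_DEFAULT = 0.8


@dataclass(frozen=True)
class SubgraphMapping:
    """One drug->protein->gene->disease match with its score and provenance."""

    drug: str
    protein: str
    gene: str
    disease: str
    raw_activity_nm: float | None
    norm_activity: float
    association_score: float
    mapping_score: float
    binds_edge: str
    encoded_edge: str
    involved_edge: str


@dataclass(frozen=True)
class InferredIndication:
    """The deduplicated drug--disease hypothesis with its best support."""

    drug: str
    disease: str
    score: float
    best_mapping: SubgraphMapping


def candidate_drugs(graph: SemanticGraph) -> set[str]:
    """Approved small molecules: the Group list contains ``approved``.

    Group is a pipe-delimited list (a drug may be both approved and
    withdrawn); matching is case-insensitive.
    """
    candidates = set()
    for node_id in graph.nodes_of_type(SMALL_MOLECULE):
        groups = {g.lower() for g in graph.node(node_id).attr_list("group")}
        if APPROVED_GROUP in groups:
            candidates.add(node_id)
    return candidates


def normalize_activity(
    value: float | None,
    missing_default: float = MISSING_ACTIVITY_DEFAULT,
    clamp_low: float = 0.0,
    clamp_high: float = 1.0,
) -> float:
    """Map an activity in nM to [0, 1]: 1 nM -> 1.0, 100 nM -> 0.8, clamped.

    A missing measurement returns ``missing_default`` (0.8).
    """
    if value is None:
        return missing_default
    if value <= 0:
        raise ValueError(f"activity must be > 0 nM, got {value}")
    return min(clamp_high, max(clamp_low, 1.0 - 0.1 * math.log10(value)))


def score_mapping(norm_activity: float, association_score: float) -> float:
    """Arithmetic mean of the two [0, 1] attribute scores."""
    for name, value in (("norm_activity", norm_activity), ("association_score", association_score)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return (norm_activity + association_score) / 2.0


def find_mappings(
    graph: SemanticGraph, candidates: Iterable[str] | None = None
) -> list[SubgraphMapping]:
    """Enumerate every instance of the four-node pattern, exhaustively.

    The output is order-independent: mappings are sorted by (drug, disease,
    -score, edge ids).  An ``involved_in`` edge without an association score
    is a hard error naming the edge.
    """
    if candidates is None:
        candidates = candidate_drugs(graph)
    mappings: list[SubgraphMapping] = []
    for drug in sorted(candidates):
        for binds in graph.out_edges(drug, BINDS_TO):
            raw = binds.attr_float(ACTIVITY_ATTR)
            norm = normalize_activity(raw)
            for encoded in graph.out_edges(binds.target, ENCODED_BY):
                for involved in graph.out_edges(encoded.target, INVOLVED_IN):
                    assoc = involved.attr_float(ASSOCIATION_SCORE_ATTR)
                    if assoc is None:
                        raise GraphError(
                            f"involved_in edge {involved.edge_id} lacks an association score"
                        )
                    mappings.append(
                        SubgraphMapping(
                            drug=drug,
                            protein=binds.target,
                            gene=encoded.target,
                            disease=involved.target,
                            raw_activity_nm=raw,
                            norm_activity=norm,
                            association_score=assoc,
                            mapping_score=score_mapping(norm, assoc),
                            binds_edge=binds.edge_id,
                            encoded_edge=encoded.edge_id,
                            involved_edge=involved.edge_id,
                        )
                    )
    mappings.sort(
        key=lambda m: (
            m.drug,
            m.disease,
            -m.mapping_score,
            m.binds_edge,
            m.encoded_edge,
            m.involved_edge,
        )
    )
    return mappings


def dedupe(mappings: Sequence[SubgraphMapping]) -> list[InferredIndication]:
    """Keep the best-scoring mapping per (drug, disease) pair.

    Score ties break by lexicographic (protein, gene, edge ids); known
    indications are *not* excluded (validation rediscovers them).
    """
    best: dict[tuple[str, str], SubgraphMapping] = {}
    n_ties = 0
    for mapping in mappings:
        key = (mapping.drug, mapping.disease)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = mapping
            continue
        order = (
            -mapping.mapping_score,
            mapping.protein,
            mapping.gene,
            mapping.binds_edge,
            mapping.encoded_edge,
            mapping.involved_edge,
        )
        incumbent_order = (
            -incumbent.mapping_score,
            incumbent.protein,
            incumbent.gene,
            incumbent.binds_edge,
            incumbent.encoded_edge,
            incumbent.involved_edge,
        )
        if mapping.mapping_score == incumbent.mapping_score:
            n_ties += 1
        if order < incumbent_order:
            best[key] = mapping
    if n_ties:
        log.info("dedupe: %d score tie(s) broken lexicographically", n_ties)
    out = [
        InferredIndication(drug, disease, m.mapping_score, m)
        for (drug, disease), m in best.items()
    ]
    out.sort(key=lambda ind: (-ind.score, ind.drug, ind.disease))
    return out
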