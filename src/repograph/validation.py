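"""Evaluation of inferred indications against known drug--disease pairs.

A known indication (drug, disease) is *identified* when the approach
inferred an indication for the same drug on the same disease or on a
disease semantically close to it (Sim >= a threshold; the exact node match
counts as Sim 1).  The working threshold 0.633 corresponds to a two-node
distance in the MeSH hierarchy.  Recall is reported against the knowns
whose drug produced at least one inference (knowns for drugs without any
mapping cannot possibly be recovered and are excluded from the
denominator).  The ROC labels each inferred indication positive iff it
matches some known at the threshold and ranks by the mapping score; the
AUC is the midrank Mann--Whitney statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from sklearn.metrics import roc_auc_score

from .graph_model import MESH_UI_ATTR, SemanticGraph
from .mesh_sim import MeshTree, SimParams, sim
from .mining import InferredIndication

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationReport:
    n_known: int
    n_known_reachable: int
    n_identified: int
    recall: float
    auc: float | None
    sim_threshold: float


def _disease_ui(graph: SemanticGraph, node_id: str) -> str | None:
    if not graph.has_node(node_id):
        return None
    return graph.node(node_id).attr(MESH_UI_ATTR)


def _matches(
    known_key: str,
    inferred_node: str,
    inferred_ui: str | None,
    tree: MeshTree,
    threshold: float,
    params: SimParams,
) -> bool:
    if known_key == inferred_node or (inferred_ui and known_key == inferred_ui):
        return True  # exact node/UI match counts as Sim 1
    if inferred_ui and known_key in tree and inferred_ui in tree:
        return sim(tree, known_key, inferred_ui, params) >= threshold
    return False


def match_known(
    inferred: Sequence[InferredIndication],
    known: set[tuple[str, str]],
    graph: SemanticGraph,
    tree: MeshTree,
    threshold: float,
    params: SimParams = SimParams(),
) -> set[tuple[str, str]]:
    """The subset of knowns identified by some same-drug inference.

    Known diseases may be given as graph node ids or MeSH UIs.
    """
    if not 0.0 <= threshold <= 1.5:
        raise ValueError("threshold out of range")
    by_drug: dict[str, list[tuple[str, str | None]]] = {}
    for indication in inferred:
        by_drug.setdefault(indication.drug, []).append(
            (indication.disease, _disease_ui(graph, indication.disease))
        )
    identified = set()
    for drug, key in known:
        for node, ui in by_drug.get(drug, ()):
            if _matches(key, node, ui, tree, threshold, params):
                identified.add((drug, key))
                break
    return identified


def reachable_known(
    inferred: Sequence[InferredIndication], known: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    """Knowns whose drug produced at least one inference."""
    drugs = {indication.drug for indication in inferred}
    return {pair for pair in known if pair[0] in drugs}


def recall_curve(
    inferred: Sequence[InferredIndication],
    known: set[tuple[str, str]],
    graph: SemanticGraph,
    tree: MeshTree,
    thresholds: Sequence[float],
    params: SimParams = SimParams(),
) -> list[tuple[float, float]]:
    """Recall per Sim threshold; a non-increasing step function."""
    reachable = reachable_known(inferred, known)
    out = []
    for threshold in thresholds:
        identified = match_known(inferred, reachable, graph, tree, threshold, params)
        recall = len(identified) / len(reachable) if reachable else 0.0
        out.append((threshold, recall))
    return out


def roc_auc(
    inferred: Sequence[InferredIndication],
    known: set[tuple[str, str]],
    graph: SemanticGraph,
    tree: MeshTree,
    threshold: float,
    params: SimParams = SimParams(),
) -> float:
    """AUC of the mapping-score ranking over matched/unmatched inferences."""
    if not inferred:
        raise ValueError("no inferred indications to evaluate")
    by_drug: dict[str, list[tuple[str, str | None]]] = {}
    for drug, key in known:
        by_drug.setdefault(drug, []).append((key, None))
    labels = []
    scores = []
    for indication in inferred:
        ui = _disease_ui(graph, indication.disease)
        positive = any(
            _matches(key, indication.disease, ui, tree, threshold, params)
            for key, _ in by_drug.get(indication.drug, ())
        )
        labels.append(1 if positive else 0)
        scores.append(indication.score)
    if min(labels) == max(labels):
        raise ValueError("single-class labeling; AUC is undefined")
    return float(roc_auc_score(labels, scores))


def evaluate(
    inferred: Sequence[InferredIndication],
    known: set[tuple[str, str]],
    graph: SemanticGraph,
    tree: MeshTree,
    threshold: float = 0.633,
    params: SimParams = SimParams(),
) -> ValidationReport:
    """Full report: recall over reachable knowns plus the ROC AUC.

    The AUC is ``None`` when the labeling is single-class (logged).
    """
    reachable = reachable_known(inferred, known)
    identified = match_known(inferred, reachable, graph, tree, threshold, params)
    try:
        auc = roc_auc(inferred, known, graph, tree, threshold, params)
    except ValueError as exc:
        log.warning("AUC unavailable: %s", exc)
        auc = None
    return ValidationReport(
        n_known=len(known),
        n_known_reachable=len(reachable),
        n_identified=len(identified),
        recall=len(identified) / len(reachable) if reachable else 0.0,
        auc=auc,
        sim_threshold=threshold,
    )
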