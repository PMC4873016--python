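"""Therapeutic-area prioritization: coverage, TAU, RTA, size eligibility.

A therapeutic area is a top-level MeSH code (C04, C10, ...); a disease
belongs to every area that prefixes one of its tree numbers, so diseases
placed in multiple branches are counted once per area.  For each area the
fraction of diseases with at least one ``involved_in`` edge (P(G-D): genetic
knowledge) and with at least one ``has_indication`` edge (P(Dr-D): marketed
treatment coverage) give two scores:

    TAU(ta) = (1 - P(Dr-D)) * P(G-D) * f(|ta|)      "unmet need"
    RTA(ta) = P(Dr-D) * P(G-D)                       "knowledge-rich"

where f is a size factor that is 1 for the largest area (default
``|ta| / MAX``), so large, well-studied but under-drugged areas score the
highest TAU.  Areas holding no more than ``1 / n_areas`` of all disease-area
memberships (3.44% for the full 29-branch MeSH) are flagged ineligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .graph_model import (
    DISEASE_TYPES,
    HAS_INDICATION,
    INVOLVED_IN,
    TREE_NUMBERS_ATTR,
    SemanticGraph,
)

log = logging.getLogger(__name__)

SIZE_FACTOR_RATIO = "ratio"  # |ta| / MAX (default reading)
SIZE_FACTOR_ONE_MINUS_RATIO = "one_minus_ratio"  # 1 - |ta| / MAX
SIZE_FACTOR_INVERSE = "inverse"  # 1 - 1 / (MAX * |ta|)
SIZE_FACTOR_MODES = (
    SIZE_FACTOR_RATIO,
    SIZE_FACTOR_ONE_MINUS_RATIO,
    SIZE_FACTOR_INVERSE,
)


@dataclass(frozen=True)
class AreaScore:
    ta: str
    n_diseases: int
    p_gd: float
    p_drd: float
    tau: float
    rta: float
    eligible: bool

    @property
    def not_p_drd(self) -> float:
        return 1.0 - self.p_drd


def area_membership(graph: SemanticGraph) -> dict[str, frozenset[str]]:
    """Map each top-level MeSH code to the diseases under it.

    Multi-area diseases appear in every area prefixing one of their tree
    numbers; diseases carrying no tree number are excluded with a warning.
    """
    members: dict[str, set[str]] = {}
    n_skipped = 0
    for disease_type in sorted(DISEASE_TYPES):
        for node_id in graph.nodes_of_type(disease_type):
            numbers = graph.node(node_id).attr_list(TREE_NUMBERS_ATTR)
            if not numbers:
                n_skipped += 1
                continue
            for number in numbers:
                members.setdefault(number.split(".")[0], set()).add(node_id)
    if n_skipped:
        log.warning("%d disease(s) without tree numbers excluded from areas", n_skipped)
    return {ta: frozenset(ids) for ta, ids in members.items()}


def coverage(graph: SemanticGraph, members: frozenset[str] | set[str]) -> tuple[float, float]:
    """(P(G-D), P(Dr-D)) for one area's disease set."""
    if not members:
        raise ValueError("coverage of an empty member set is undefined")
    n_gd = sum(1 for d in members if graph.has_edge_of_type(d, INVOLVED_IN, "in"))
    n_drd = sum(1 for d in members if graph.has_edge_of_type(d, HAS_INDICATION, "in"))
    return n_gd / len(members), n_drd / len(members)


def size_factor(n_diseases: int, max_size: int, mode: str = SIZE_FACTOR_RATIO) -> float:
    if max_size <= 0:
        raise ValueError("max_size must be > 0")
    if mode == SIZE_FACTOR_RATIO:
        return n_diseases / max_size
    if mode == SIZE_FACTOR_ONE_MINUS_RATIO:
        return 1.0 - n_diseases / max_size
    if mode == SIZE_FACTOR_INVERSE:
        return 1.0 - 1.0 / (max_size * n_diseases)
    raise ValueError(f"unknown size-factor mode {mode!r}")


def tau(
    p_gd: float,
    p_drd: float,
    n_diseases: int,
    max_size: int,
    size_factor_mode: str = SIZE_FACTOR_RATIO,
) -> float:
    """Therapeutic-area unmet score in [0, 1]."""
    return (1.0 - p_drd) * p_gd * size_factor(n_diseases, max_size, size_factor_mode)


def rta(p_gd: float, p_drd: float) -> float:
    """Rich-therapeutic-area score in [0, 1]."""
    return p_drd * p_gd


def eligible_areas(
    sizes: Mapping[str, int], n_areas: int | None = None
) -> dict[str, bool]:
    """Size filter: eligible iff the area's share strictly exceeds 1/n_areas.

    ``sizes`` counts disease-area memberships with duplication (a disease
    counts once per area it belongs to); ``n_areas`` defaults to the number
    of areas present (29 for the full MeSH disease forest, giving the 3.44%
    threshold).
    """
    total = sum(sizes.values())
    if n_areas is None:
        n_areas = len(sizes)
    if n_areas <= 0 or total <= 0:
        return {ta: False for ta in sizes}
    threshold = 1.0 / n_areas
    return {ta: (size / total) > threshold for ta, size in sizes.items()}


def score_areas(
    graph: SemanticGraph,
    size_factor_mode: str = SIZE_FACTOR_RATIO,
    n_areas: int | None = None,
) -> list[AreaScore]:
    """Full area ranking, sorted by TAU descending (deterministic)."""
    members = area_membership(graph)
    if not members:
        return []
    sizes = {ta: len(ids) for ta, ids in members.items()}
    max_size = max(sizes.values())
    eligibility = eligible_areas(sizes, n_areas)
    scores = []
    for ta in sorted(members):
        p_gd, p_drd = coverage(graph, members[ta])
        scores.append(
            AreaScore(
                ta=ta,
                n_diseases=sizes[ta],
                p_gd=p_gd,
                p_drd=p_drd,
                tau=tau(p_gd, p_drd, sizes[ta], max_size, size_factor_mode),
                rta=rta(p_gd, p_drd),
                eligible=eligibility[ta],
            )
        )
    scores.sort(key=lambda s: (-s.tau, s.ta))
    return scores
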