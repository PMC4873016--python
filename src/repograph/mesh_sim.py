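"""MeSH disease hierarchy and the path-based semantic similarity ``Sim``.

MeSH encodes each disease's position(s) in a forest of dot-delimited tree
numbers (e.g. ``C10.228.140``).  The similarity between two diseases follows
the Leacock--Chodorow construction:

    Sim(a, b) = -log(Dist(a, b) / (2 * depth)) / MAX,   MAX = log(2 * depth)

which simplifies to ``1 - log(Dist) / log(2 * depth)``; the log base cancels.
``Dist`` is the shortest path length between the two concepts counted in
*nodes* (an identical concept has Dist 1, a parent--child pair Dist 2) and
``depth`` is the maximum depth of the hierarchy, 10 by default.  Under this
parameterization a parent--child pair scores 0.768, a two-node distance
0.633 and a nine-node distance 0.231 (values truncated to three decimals).
Diseases whose tree numbers share no common prefix are in different branches
of the forest and score 0.

A disease may carry several tree numbers (synonymous placements in multiple
parts of the taxonomy); the distance is the minimum over all placement
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

NODE_CONVENTION = "node"
EDGE_CONVENTION = "edge"


@dataclass(frozen=True)
class SimParams:
    """Parameters of the similarity measure.

    depth
        Maximum depth of the hierarchy; sets the saturation distance
        ``2 * depth`` at which similarity reaches 0.
    dist_convention
        ``"node"`` counts nodes on the shortest path (identical = 1,
        parent--child = 2); ``"edge"`` counts edges (identical = 0).
    """

    depth: int = 10
    dist_convention: str = NODE_CONVENTION

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.dist_convention not in (NODE_CONVENTION, EDGE_CONVENTION):
            raise ValueError(f"unknown distance convention {self.dist_convention!r}")

    @property
    def max_score(self) -> float:
        """MAX of the similarity formula: log of twice the hierarchy depth."""
        return math.log(2 * self.depth)


class MeshTree:
    """The disease vocabulary: MeSH UI -> heading + set of tree numbers."""

    def __init__(self, entries: Mapping[str, tuple[str, Iterable[str]]]) -> None:
        self._entries: dict[str, tuple[str, tuple[str, ...]]] = {}
        for ui, (heading, numbers) in entries.items():
            ordered = tuple(sorted(set(numbers)))
            self._entries[ui] = (heading, ordered)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeshTree":
        """Read ``mesh.tsv``: ``mesh_ui, heading, tree_numbers`` (pipe-delimited).

        A converter from the NLM descriptor ASCII export would populate the
        same three columns from the ``UI =``, ``MH =`` and ``MN =`` records.
        """
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries = {
            row.mesh_ui: (row.heading, [t for t in row.tree_numbers.split("|") if t])
            for row in frame.itertuples(index=False)
        }
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("mesh_ui\theading\ttree_numbers\n")
            for ui in sorted(self._entries):
                heading, numbers = self._entries[ui]
                handle.write(f"{ui}\t{heading}\t{'|'.join(numbers)}\n")

    def __contains__(self, ui: str) -> bool:
        return ui in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def uis(self) -> list[str]:
        return sorted(self._entries)

    def heading(self, ui: str) -> str:
        return self._entries[ui][0]

    def tree_numbers(self, ui: str) -> tuple[str, ...]:
        return self._entries[ui][1]


def _check_ui(tree: MeshTree, ui: str) -> None:
    if ui not in tree:
        raise KeyError(f"unknown MeSH UI {ui!r}")


def node_distance(tree: MeshTree, a: str, b: str) -> int | None:
    """Shortest path between two concepts, counted in nodes.

    For every pair of tree numbers of ``a`` and ``b`` that share a common
    prefix, the path runs up from each placement to the longest common
    prefix; the distance is the minimum over all pairs of (levels up from
    ``a``) + (levels up from ``b``) + 1.  Identical concepts are at distance
    1.  Returns ``None`` when no placement pair shares any prefix
    (unreachable across branches of the forest).
    """
    _check_ui(tree, a)
    _check_ui(tree, b)
    if a == b:
        return 1
    best: int | None = None
    for ta in tree.tree_numbers(a):
        segs_a = ta.split(".")
        for tb in tree.tree_numbers(b):
            segs_b = tb.split(".")
            shared = 0
            for seg_a, seg_b in zip(segs_a, segs_b):
                if seg_a != seg_b:
                    break
                shared += 1
            if shared == 0:
                continue
            edges = (len(segs_a) - shared) + (len(segs_b) - shared)
            if best is None or edges < best:
                best = edges
    return None if best is None else best + 1


def sim(tree: MeshTree, a: str, b: str, params: SimParams = SimParams()) -> float:
    """Semantic similarity in [0, 1]; symmetric; 0 for unreachable pairs."""
    dist = node_distance(tree, a, b)
    if dist is None:
        return 0.0
    if params.dist_convention == EDGE_CONVENTION:
        dist -= 1
        if dist <= 0:
            return 1.0
    value = 1.0 - math.log(dist) / math.log(2 * params.depth)
    return min(1.0, max(0.0, value))


def truncate(value: float, decimals: int = 3) -> float:
    """Truncate (not round) toward zero; 0.76862 -> 0.768."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor


def forest_graph(tree: MeshTree) -> nx.Graph:
    """Undirected graph over tree-number positions, parent--child edges only.

    Positions implied by a tree number but carrying no disease of their own
    are synthesized as unlabeled nodes, so paths through them are available.
    Used as the independent shortest-path oracle in tests and by the
    synthetic-fixture generator to plant diseases at exact distances.
    """
    graph = nx.Graph()
    for ui in tree.uis():
        for number in tree.tree_numbers(ui):
            segs = number.split(".")
            for level in range(1, len(segs) + 1):
                position = ".".join(segs[:level])
                graph.add_node(position)
                if level > 1:
                    graph.add_edge(".".join(segs[: level - 1]), position)
    return graph
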