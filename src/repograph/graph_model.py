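"""In-memory typed property graph for drug-repositioning data.

Nodes are small-molecule drugs, proteins, genes and diseases (common or
rare); edges come from a closed set of typed relations.  Every edge type has
a fixed endpoint signature that is enforced on construction, so a validated
graph can only contain well-formed drug -> protein -> gene -> disease chains
plus drug--disease annotations (``has_indication`` / ``has_side_effect``)
and disease-hierarchy relations.

The graph is backed by a :class:`networkx.MultiDiGraph`; parallel edges of
the same type between the same endpoints are first-class (a drug--protein
pair may carry several independent activity measurements).  Attribute values
are stored as text with typed accessors so unknown attributes survive
serialization round-trips unchanged.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

# -- closed type sets -------------------------------------------------------

SMALL_MOLECULE = "Small_Molecule"
PROTEIN = "Protein"
GENE = "Gene"
COMMON_DISEASE = "Common_Disease"
RARE_DISEASE = "Rare_Disease"

NODE_TYPES = frozenset(
    {SMALL_MOLECULE, PROTEIN, GENE, COMMON_DISEASE, RARE_DISEASE}
)
DISEASE_TYPES = frozenset({COMMON_DISEASE, RARE_DISEASE})

BINDS_TO = "binds_to"
ENCODED_BY = "encoded_by"
INVOLVED_IN = "involved_in"
HAS_INDICATION = "has_indication"
HAS_SIDE_EFFECT = "has_side_effect"
IS_A = "is_a"
PART_OF = "part_of"
HAS_PARENT = "has_parent"

EDGE_TYPES = frozenset(
    {
        BINDS_TO,
        ENCODED_BY,
        INVOLVED_IN,
        HAS_INDICATION,
        HAS_SIDE_EFFECT,
        IS_A,
        PART_OF,
        HAS_PARENT,
    }
)

#: endpoint signature of every edge type: (allowed source types, allowed
#: target types)
EDGE_SIGNATURES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    BINDS_TO: (frozenset({SMALL_MOLECULE}), frozenset({PROTEIN})),
    ENCODED_BY: (frozenset({PROTEIN}), frozenset({GENE})),
    INVOLVED_IN: (frozenset({GENE}), DISEASE_TYPES),
    HAS_INDICATION: (frozenset({SMALL_MOLECULE}), DISEASE_TYPES),
    HAS_SIDE_EFFECT: (frozenset({SMALL_MOLECULE}), DISEASE_TYPES),
    IS_A: (DISEASE_TYPES, DISEASE_TYPES),
    PART_OF: (frozenset({RARE_DISEASE}), frozenset({RARE_DISEASE})),
    HAS_PARENT: (frozenset({RARE_DISEASE}), frozenset({RARE_DISEASE})),
}

#: attribute keys with a numeric contract (parsed lazily, validated > 0)
ACTIVITY_ATTR = "activity_nm"
ASSOCIATION_SCORE_ATTR = "association_score"
DIRECTIONALITY_ATTR = "directionality"
ACTION_ATTR = "action"
MESH_UI_ATTR = "mesh_ui"
TREE_NUMBERS_ATTR = "tree_numbers"


class GraphError(ValueError):
    """A structural violation of the typed-graph contract."""


@dataclass(frozen=True)
class NodeRecord:
    """One typed node with its free-form text attributes."""

    id: str
    node_type: str
    attributes: Mapping[str, str]

    def attr(self, key: str, default: str | None = None) -> str | None:
        return self.attributes.get(key, default)

    def attr_list(self, key: str) -> list[str]:
        """A pipe-delimited list attribute (e.g. MeSH tree numbers)."""
        raw = self.attributes.get(key, "")
        return [item for item in raw.split("|") if item]

    def attr_float(self, key: str) -> float | None:
        raw = self.attributes.get(key)
        return None if raw in (None, "") else float(raw)


@dataclass(frozen=True)
class EdgeRecord:
    """One typed, attributed edge; ``edge_id`` is unique within a graph."""

    edge_id: str
    source: str
    target: str
    edge_type: str
    attributes: Mapping[str, str]

    def attr(self, key: str, default: str | None = None) -> str | None:
        return self.attributes.get(key, default)

    def attr_float(self, key: str) -> float | None:
        raw = self.attributes.get(key)
        return None if raw in (None, "") else float(raw)


class SemanticGraph:
    """Typed property graph with indexes by node type and endpoint.

    Mutating helpers (:func:`merge_rare_disease_synonyms`) return new graph
    values; shared inputs are never silently mutated.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._by_type: dict[str, set[str]] = {t: set() for t in NODE_TYPES}
        self._edge_endpoints: dict[str, tuple[str, str]] = {}
        self._next_edge = 0

    # -- construction ------------------------------------------------------

    def add_node(
        self,
        node_id: str,
        node_type: str,
        attributes: Mapping[str, str] | None = None,
    ) -> None:
        if node_type not in NODE_TYPES:
            raise GraphError(f"unknown node type {node_type!r} for node {node_id!r}")
        if not node_id:
            raise GraphError("node id must be non-empty")
        if self._g.has_node(node_id):
            raise GraphError(f"duplicate node id {node_id!r}")
        attrs = {str(k): str(v) for k, v in (attributes or {}).items()}
        self._g.add_node(node_id, node_type=node_type, attributes=attrs)
        self._by_type[node_type].add(node_id)

    def add_edge(
        self,
        source: str,
        target: str,
        edge_type: str,
        attributes: Mapping[str, str] | None = None,
        edge_id: str | None = None,
    ) -> str:
        if edge_type not in EDGE_TYPES:
            raise GraphError(
                f"unknown edge type {edge_type!r} for edge {source!r}->{target!r}"
            )
        for endpoint in (source, target):
            if not self._g.has_node(endpoint):
                raise GraphError(
                    f"dangling endpoint {endpoint!r} on "
                    f"{edge_type} edge {source!r}->{target!r}"
                )
        src_types, dst_types = EDGE_SIGNATURES[edge_type]
        st = self._g.nodes[source]["node_type"]
        tt = self._g.nodes[target]["node_type"]
        if st not in src_types or tt not in dst_types:
            raise GraphError(
                f"{edge_type} edge {source!r}({st})->{target!r}({tt}) violates "
                f"signature {sorted(src_types)}->{sorted(dst_types)}"
            )
        attrs = {str(k): str(v) for k, v in (attributes or {}).items()}
        raw_activity = attrs.get(ACTIVITY_ATTR)
        if raw_activity not in (None, ""):
            try:
                value = float(raw_activity)
            except ValueError as exc:
                raise GraphError(
                    f"non-numeric {ACTIVITY_ATTR}={raw_activity!r} on edge "
                    f"{source!r}->{target!r}"
                ) from exc
            if value <= 0:
                raise GraphError(
                    f"{ACTIVITY_ATTR} must be > 0, got {value} on edge "
                    f"{source!r}->{target!r}"
                )
        if edge_id is None:
            edge_id = f"e{self._next_edge:06d}"
            self._next_edge += 1
        if edge_id in self._edge_endpoints:
            raise GraphError(f"duplicate edge id {edge_id!r}")
        self._g.add_edge(source, target, key=edge_id, edge_type=edge_type, attributes=attrs)
        self._edge_endpoints[edge_id] = (source, target)
        return edge_id

    def _remove_edge(self, edge_id: str) -> None:
        source, target = self._edge_endpoints.pop(edge_id)
        self._g.remove_edge(source, target, key=edge_id)

    def _remove_node(self, node_id: str) -> None:
        for rec in list(self.in_edges(node_id)) + list(self.out_edges(node_id)):
            if rec.edge_id in self._edge_endpoints:
                self._remove_edge(rec.edge_id)
        node_type = self._g.nodes[node_id]["node_type"]
        self._by_type[node_type].discard(node_id)
        self._g.remove_node(node_id)

    def _set_attributes(self, node_id: str, attributes: Mapping[str, str]) -> None:
        self._g.nodes[node_id]["attributes"] = {
            str(k): str(v) for k, v in attributes.items()
        }

    # -- accessors ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, node_id: str) -> bool:
        return self._g.has_node(node_id)

    def node(self, node_id: str) -> NodeRecord:
        if not self._g.has_node(node_id):
            raise GraphError(f"unknown node {node_id!r}")
        data = self._g.nodes[node_id]
        return NodeRecord(node_id, data["node_type"], dict(data["attributes"]))

    def nodes(self) -> Iterator[NodeRecord]:
        for node_id in sorted(self._g.nodes):
            yield self.node(node_id)

    def nodes_of_type(self, node_type: str) -> list[str]:
        if node_type not in NODE_TYPES:
            raise GraphError(f"unknown node type {node_type!r}")
        return sorted(self._by_type[node_type])

    def node_type(self, node_id: str) -> str:
        return self.node(node_id).node_type

    def edge(self, edge_id: str) -> EdgeRecord:
        if edge_id not in self._edge_endpoints:
            raise GraphError(f"unknown edge {edge_id!r}")
        source, target = self._edge_endpoints[edge_id]
        data = self._g.edges[source, target, edge_id]
        return EdgeRecord(edge_id, source, target, data["edge_type"], dict(data["attributes"]))

    def edges(self, edge_type: str | None = None) -> list[EdgeRecord]:
        records = [
            EdgeRecord(key, u, v, data["edge_type"], dict(data["attributes"]))
            for u, v, key, data in self._g.edges(keys=True, data=True)
            if edge_type is None or data["edge_type"] == edge_type
        ]
        records.sort(key=lambda rec: rec.edge_id)
        return records

    def out_edges(self, node_id: str, edge_type: str | None = None) -> list[EdgeRecord]:
        if not self._g.has_node(node_id):
            raise GraphError(f"unknown node {node_id!r}")
        records = [
            EdgeRecord(key, u, v, data["edge_type"], dict(data["attributes"]))
            for u, v, key, data in self._g.out_edges(node_id, keys=True, data=True)
            if edge_type is None or data["edge_type"] == edge_type
        ]
        records.sort(key=lambda rec: rec.edge_id)
        return records

    def in_edges(self, node_id: str, edge_type: str | None = None) -> list[EdgeRecord]:
        if not self._g.has_node(node_id):
            raise GraphError(f"unknown node {node_id!r}")
        records = [
            EdgeRecord(key, u, v, data["edge_type"], dict(data["attributes"]))
            for u, v, key, data in self._g.in_edges(node_id, keys=True, data=True)
            if edge_type is None or data["edge_type"] == edge_type
        ]
        records.sort(key=lambda rec: rec.edge_id)
        return records

    def has_edge_of_type(self, node_id: str, edge_type: str, direction: str = "in") -> bool:
        records = self.in_edges(node_id, edge_type) if direction == "in" else self.out_edges(node_id, edge_type)
        return bool(records)

    # -- structural operations --------------------------------------------

    def copy(self) -> "SemanticGraph":
        clone = SemanticGraph()
        for rec in self.nodes():
            clone.add_node(rec.id, rec.node_type, rec.attributes)
        for rec in self.edges():
            clone.add_edge(rec.source, rec.target, rec.edge_type, rec.attributes, edge_id=rec.edge_id)
        clone._next_edge = self._next_edge
        return clone

    def remove_isolated(self) -> int:
        """Drop nodes without any incident edge; returns the count removed."""
        isolated = [n for n in self._g.nodes if self._g.degree(n) == 0]
        for node_id in isolated:
            self._remove_node(node_id)
        return len(isolated)

    def validate(self) -> None:
        """Re-check every structural invariant; raises :class:`GraphError`."""
        for node_id, data in self._g.nodes(data=True):
            if data["node_type"] not in NODE_TYPES:
                raise GraphError(f"unknown node type on {node_id!r}")
            if data["node_type"] == COMMON_DISEASE and not data["attributes"].get(MESH_UI_ATTR):
                raise GraphError(f"Common_Disease {node_id!r} lacks a MeSH UI")
        for rec in self.edges():
            src_types, dst_types = EDGE_SIGNATURES[rec.edge_type]
            if self.node_type(rec.source) not in src_types or self.node_type(rec.target) not in dst_types:
                raise GraphError(
                    f"edge {rec.edge_id} ({rec.edge_type}) violates its endpoint signature"
                )
            raw = rec.attributes.get(ACTIVITY_ATTR)
            if raw not in (None, "") and float(raw) <= 0:
                raise GraphError(f"edge {rec.edge_id} has non-positive {ACTIVITY_ATTR}")

    def to_networkx(self) -> nx.MultiDiGraph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SemanticGraph):
            return NotImplemented
        mine = {(r.id, r.node_type, tuple(sorted(r.attributes.items()))) for r in self.nodes()}
        theirs = {(r.id, r.node_type, tuple(sorted(r.attributes.items()))) for r in other.nodes()}
        if mine != theirs:
            return False
        mine_e = {
            (r.edge_id, r.source, r.target, r.edge_type, tuple(sorted(r.attributes.items())))
            for r in self.edges()
        }
        theirs_e = {
            (r.edge_id, r.source, r.target, r.edge_type, tuple(sorted(r.attributes.items())))
            for r in other.edges()
        }
        return mine_e == theirs_e

    def __repr__(self) -> str:
        return f"SemanticGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- serialization ----------------------------------------------------------


def _format_attributes(attrs: Mapping[str, str]) -> str:
    return ";".join(
        f"{key}={urllib.parse.quote(str(value), safe='')}"
        for key, value in sorted(attrs.items())
    )


def _parse_attributes(block: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if not block:
        return out
    for item in block.split(";"):
        if not item:
            continue
        key, sep, value = item.partition("=")
        if not sep:
            raise GraphError(f"malformed attribute item {item!r}")
        out[key] = urllib.parse.unquote(value)
    return out


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_graph(nodes_table: str | Path, edges_table: str | Path | None = None) -> SemanticGraph:
    """Load a graph from the two-file TSV layout (or the edge-list dialect).

    The two-file layout is ``nodes.tsv`` (``id, node_type, attributes``) plus
    ``edges.tsv`` (``edge_id, source_id, target_id, edge_type, attributes``);
    attribute blocks are semicolon-delimited ``key=value`` items with
    URL-escaped values.  A single-file edge-list dialect with node attributes
    repeated per row is auto-detected by its header.  After loading, isolated
    nodes are removed (their count is logged) and all invariants re-checked.
    """
    frame = _read_tsv(nodes_table)
    if "source_id" in frame.columns and "node_type" not in frame.columns:
        graph = _load_edge_list(frame)
    else:
        if edges_table is None:
            raise GraphError("edges_table is required for the two-file layout")
        graph = _load_two_file(frame, _read_tsv(edges_table))
    dropped = graph.remove_isolated()
    if dropped:
        log.info("load_graph: removed %d unconnected node(s)", dropped)
    graph.validate()
    return graph


def _load_two_file(ndf: pd.DataFrame, edf: pd.DataFrame) -> SemanticGraph:
    graph = SemanticGraph()
    for i, row in enumerate(ndf.itertuples(index=False), start=2):
        try:
            graph.add_node(row.id, row.node_type, _parse_attributes(row.attributes))
        except GraphError as exc:
            raise GraphError(f"{ndf.attrs.get('path', 'nodes table')} row {i}: {exc}") from exc
    has_ids = "edge_id" in edf.columns
    for i, row in enumerate(edf.itertuples(index=False), start=2):
        try:
            graph.add_edge(
                row.source_id,
                row.target_id,
                row.edge_type,
                _parse_attributes(row.attributes),
                edge_id=row.edge_id if has_ids else None,
            )
        except GraphError as exc:
            raise GraphError(f"edges table row {i}: {exc}") from exc
    return graph


def _load_edge_list(frame: pd.DataFrame) -> SemanticGraph:
    """Single-file dialect: node attributes are repeated on every edge row.

    Columns: ``source_id, source_type, source_attributes, target_id,
    target_type, target_attributes, edge_type, attributes``.  The first
    occurrence of a node defines its attributes.
    """
    graph = SemanticGraph()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            for node_id, node_type, block in (
                (row.source_id, row.source_type, row.source_attributes),
                (row.target_id, row.target_type, row.target_attributes),
            ):
                if not graph.has_node(node_id):
                    graph.add_node(node_id, node_type, _parse_attributes(block))
            graph.add_edge(
                row.source_id, row.target_id, row.edge_type, _parse_attributes(row.attributes)
            )
        except GraphError as exc:
            raise GraphError(f"edge-list row {i}: {exc}") from exc
    return graph


def save_graph(
    graph: SemanticGraph, nodes_table: str | Path, edges_table: str | Path
) -> None:
    """Write the two-file TSV layout; ``load_graph`` round-trips it exactly."""
    with open(nodes_table, "w", encoding="utf-8") as handle:
        handle.write("id\tnode_type\tattributes\n")
        for rec in graph.nodes():
            handle.write(f"{rec.id}\t{rec.node_type}\t{_format_attributes(rec.attributes)}\n")
    with open(edges_table, "w", encoding="utf-8") as handle:
        handle.write("edge_id\tsource_id\ttarget_id\tedge_type\tattributes\n")
        for rec in graph.edges():
            handle.write(
                f"{rec.edge_id}\t{rec.source}\t{rec.target}\t{rec.edge_type}\t"
                f"{_format_attributes(rec.attributes)}\n"
            )


def export_graphml(graph: SemanticGraph, path: str | Path) -> None:
    """Export to GraphML for graph databases and visualizers."""
    out = nx.MultiDiGraph()
    for rec in graph.nodes():
        out.add_node(rec.id, node_type=rec.node_type, **dict(rec.attributes))
    for rec in graph.edges():
        out.add_edge(rec.source, rec.target, key=rec.edge_id, edge_type=rec.edge_type, **dict(rec.attributes))
    nx.write_graphml(out, path)


def merge_rare_disease_synonyms(graph: SemanticGraph) -> SemanticGraph:
    """Fold common-disease nodes into rare diseases that cite them as synonyms.

    Wherever a ``Rare_Disease`` carries a ``mesh_ui`` attribute that is also
    the MeSH UI of a ``Common_Disease`` node, the common node is merged into
    the rare one: all edges are re-pointed, the attribute union is kept (the
    rare disease's own values win on conflict) and the common node removed.
    Total edge count is preserved; node count drops by the number of merges.

    Two rare diseases claiming the same MeSH UI merge into the first by
    id order; the conflict is logged as a warning.
    """
    merged = graph.copy()
    common_by_ui: dict[str, str] = {}
    for node_id in merged.nodes_of_type(COMMON_DISEASE):
        ui = merged.node(node_id).attr(MESH_UI_ATTR)
        if ui:
            common_by_ui.setdefault(ui, node_id)
    claimed: dict[str, str] = {}
    n_merges = 0
    for rare_id in merged.nodes_of_type(RARE_DISEASE):
        ui = merged.node(rare_id).attr(MESH_UI_ATTR)
        if not ui:
            continue
        if ui in claimed:
            log.warning(
                "rare diseases %s and %s both claim MeSH UI %s; merged into %s",
                claimed[ui], rare_id, ui, claimed[ui],
            )
            continue
        common_id = common_by_ui.get(ui)
        if common_id is None:
            continue
        claimed[ui] = rare_id
        union = {**merged.node(common_id).attributes, **merged.node(rare_id).attributes}
        merged._set_attributes(rare_id, union)
        repointed = {
            rec.edge_id: rec
            for rec in merged.in_edges(common_id) + merged.out_edges(common_id)
        }
        for rec in repointed.values():
            merged._remove_edge(rec.edge_id)
            source = rare_id if rec.source == common_id else rec.source
            target = rare_id if rec.target == common_id else rec.target
            merged.add_edge(source, target, rec.edge_type, rec.attributes, edge_id=rec.edge_id)
        merged._remove_node(common_id)
        n_merges += 1
    if n_merges:
        log.info("merged %d rare-disease MeSH synonym(s)", n_merges)
    return merged
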