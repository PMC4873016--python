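"""Independent brute-force oracles and random-graph builders for tests.

Everything here is deliberately naive and kept independent of the code
paths it checks: the mapping oracle enumerates all typed node quadruples,
the weighted-sum and LLS oracles are explicit arithmetic, and the distance
oracle is breadth-first search over the explicit position forest.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from repograph.graph_model import (
    BINDS_TO,
    COMMON_DISEASE,
    ENCODED_BY,
    GENE,
    INVOLVED_IN,
    PROTEIN,
    SMALL_MOLECULE,
    SemanticGraph,
)
from repograph.mesh_sim import MeshTree, forest_graph
from repograph.mining import normalize_activity, score_mapping


def ws_oracle(contributions, D):
    total = 0.0
    divisor = 1.0
    for c in contributions:
        total += c / divisor
        divisor *= D
    return total


def lls_oracle(pos_in, neg_in, pos_total, neg_total):
    return math.log((pos_in / neg_in) / (pos_total / neg_total))


def mesh_distance_oracle(tree: MeshTree, a: str, b: str) -> int | None:
    """Node-count distance via BFS on the explicit position forest."""
    if a == b:
        return 1
    forest = forest_graph(tree)
    best = None
    for pa in tree.tree_numbers(a):
        for pb in tree.tree_numbers(b):
            try:
                d = nx.shortest_path_length(forest, pa, pb)
            except nx.NetworkXNoPath:
                continue
            if best is None or d < best:
                best = d
    return None if best is None else best + 1


def naive_find_mappings(graph: SemanticGraph):
    """Test every (drug, protein, gene, disease) 4-tuple for the three typed
    edges; one result per edge combination (parallel edges included)."""
    by_pair = {BINDS_TO: {}, ENCODED_BY: {}, INVOLVED_IN: {}}
    for rec in graph.edges():
        if rec.edge_type in by_pair:
            by_pair[rec.edge_type].setdefault((rec.source, rec.target), []).append(rec)
    drugs = [
        d for d in graph.nodes_of_type(SMALL_MOLECULE)
        if "approved" in {g.lower() for g in graph.node(d).attr_list("group")}
    ]
    diseases = graph.nodes_of_type(COMMON_DISEASE) + graph.nodes_of_type("Rare_Disease")
    results = []
    for drug in drugs:
        for protein in graph.nodes_of_type(PROTEIN):
            for binds in by_pair[BINDS_TO].get((drug, protein), []):
                for gene in graph.nodes_of_type(GENE):
                    for encoded in by_pair[ENCODED_BY].get((protein, gene), []):
                        for disease in diseases:
                            for involved in by_pair[INVOLVED_IN].get((gene, disease), []):
                                raw = binds.attr_float("activity_nm")
                                norm = normalize_activity(raw)
                                assoc = involved.attr_float("association_score")
                                results.append(
                                    (
                                        drug, protein, gene, disease,
                                        binds.edge_id, encoded.edge_id, involved.edge_id,
                                        round(score_mapping(norm, assoc), 12),
                                    )
                                )
    return sorted(results)


def random_mining_graph(rng: np.random.Generator, scale: float = 1.0) -> SemanticGraph:
    """A random typed graph with parallel binds_to edges and mixed attributes."""
    n_drugs = int(rng.integers(2, max(3, int(8 * scale))))
    n_proteins = int(rng.integers(2, max(3, int(10 * scale))))
    n_genes = int(rng.integers(2, max(3, int(10 * scale))))
    n_diseases = int(rng.integers(2, max(3, int(12 * scale))))
    graph = SemanticGraph()
    for i in range(n_drugs):
        group = "approved" if rng.random() < 0.7 else "experimental"
        if rng.random() < 0.2:
            group += "|withdrawn"
        graph.add_node(f"drug{i}", SMALL_MOLECULE, {"group": group})
    for i in range(n_proteins):
        graph.add_node(f"prot{i}", PROTEIN)
    for i in range(n_genes):
        graph.add_node(f"gene{i}", GENE, {"symbol": f"gene{i}"})
    for i in range(n_diseases):
        graph.add_node(f"dis{i}", COMMON_DISEASE, {"mesh_ui": f"D{i:06d}"})
    for _ in range(int(rng.integers(1, 3 * n_drugs + 1))):
        drug = f"drug{rng.integers(n_drugs)}"
        protein = f"prot{rng.integers(n_proteins)}"
        attrs = {}
        if rng.random() < 0.7:
            attrs["activity_nm"] = f"{10 ** rng.uniform(0, 8):.6g}"
        graph.add_edge(drug, protein, BINDS_TO, attrs)
    for i in range(n_proteins):
        if rng.random() < 0.8:
            graph.add_edge(f"prot{i}", f"gene{rng.integers(n_genes)}", ENCODED_BY)
    for _ in range(int(rng.integers(1, 2 * n_genes + 1))):
        graph.add_edge(
            f"gene{rng.integers(n_genes)}",
            f"dis{rng.integers(n_diseases)}",
            INVOLVED_IN,
            {"association_score": f"{rng.random():.6f}"},
        )
    return graph
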