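import itertools

import pytest

from repograph.filters import (
    FilterConfig,
    filter_adme,
    filter_directionality,
    filter_side_effects,
    load_action_sets,
    load_adme_genes,
    run_cascade,
    save_action_sets,
)
from repograph.graph_model import (
    COMMON_DISEASE,
    GENE,
    PROTEIN,
    SMALL_MOLECULE,
    SemanticGraph,
)
from repograph.mesh_sim import MeshTree
from repograph.mining import find_mappings


@pytest.fixture()
def se_tree():
    return MeshTree(
        {
            "D_parent": ("parent", ["C10.228"]),
            "D_child": ("child", ["C10.228.140"]),
            "D_sibling": ("sibling", ["C10.228.200"]),
            "D_far": ("far", ["C04.100"]),
        }
    )


def chain(graph, drug, disease_ui, action="", directionality="unknown", gene=None):
    """Add one full drug -> protein -> gene -> disease chain."""
    gene = gene or f"g_{drug}"
    protein = f"p_{drug}"
    graph.add_node(drug, SMALL_MOLECULE, {"group": "approved"})
    graph.add_node(protein, PROTEIN)
    if not graph.has_node(gene):
        graph.add_node(gene, GENE, {"symbol": gene})
    if not graph.has_node(disease_ui):
        graph.add_node(disease_ui, COMMON_DISEASE, {"mesh_ui": disease_ui})
    attrs = {"activity_nm": "1"}
    if action:
        attrs["action"] = action
    graph.add_edge(drug, protein, "binds_to", attrs)
    graph.add_edge(protein, gene, "encoded_by")
    graph.add_edge(
        gene, disease_ui, "involved_in",
        {"association_score": "0.9", "directionality": directionality},
    )


def add_side_effect(graph, drug, disease_ui):
    if not graph.has_node(disease_ui):
        graph.add_node(disease_ui, COMMON_DISEASE, {"mesh_ui": disease_ui})
    graph.add_edge(drug, disease_ui, "has_side_effect")


class TestSideEffectFilter:
    def build(self, inferred_ui, side_effect_ui=None):
        graph = SemanticGraph()
        chain(graph, "drug", inferred_ui)
        if side_effect_ui is not None:
            add_side_effect(graph, "drug", side_effect_ui)
        return graph, find_mappings(graph)

    def test_no_side_effects_keeps_all(self, se_tree):
        graph, mappings = self.build("D_child")
        kept, removed = filter_side_effects(mappings, graph, se_tree)
        assert kept == mappings and removed == []

    def test_exact_match_removed(self, se_tree):
        graph, mappings = self.build("D_child", "D_child")
        kept, removed = filter_side_effects(mappings, graph, se_tree)
        assert kept == [] and len(removed) == 1

    def test_parent_of_side_effect_removed_at_default_et(self, se_tree):
        # Sim(parent, child) = 0.768 >= ET
        graph, mappings = self.build("D_parent", "D_child")
        kept, removed = filter_side_effects(mappings, graph, se_tree)
        assert kept == [] and len(removed) == 1

    def test_two_node_distance_kept_at_default_et(self, se_tree):
        # siblings: Sim = 0.633 < 0.768
        graph, mappings = self.build("D_child", "D_sibling")
        kept, removed = filter_side_effects(mappings, graph, se_tree)
        assert len(kept) == 1 and removed == []

    def test_et_above_one_removes_exact_matches_only(self, se_tree):
        config = FilterConfig(equivalence_threshold=1.01)
        graph, mappings = self.build("D_parent", "D_child")
        kept, _ = filter_side_effects(mappings, graph, se_tree, config)
        assert len(kept) == 1
        graph, mappings = self.build("D_child", "D_child")
        kept, _ = filter_side_effects(mappings, graph, se_tree, config)
        assert kept == []

    def test_removal_set_monotone_in_et(self, se_tree):
        graph = SemanticGraph()
        chain(graph, "drug", "D_parent")
        add_side_effect(graph, "drug", "D_child")
        add_side_effect(graph, "drug", "D_far")
        mappings = find_mappings(graph)
        previous = None
        for et in (0.1, 0.5, 0.768, 0.9, 1.01):
            _, removed = filter_side_effects(
                mappings, graph, se_tree, FilterConfig(equivalence_threshold=et)
            )
            if previous is not None:
                assert set(removed) <= set(previous)
            previous = removed

    def test_disease_without_mesh_ui_uses_exact_match_only(self, se_tree):
        graph = SemanticGraph()
        chain(graph, "drug", "D_child")
        # a side-effect disease with no usable MeSH UI
        graph.add_node("X_no_ui", COMMON_DISEASE, {"mesh_ui": "X_no_ui"})
        graph.add_edge("drug", "X_no_ui", "has_side_effect")
        mappings = find_mappings(graph)
        kept, _ = filter_side_effects(mappings, graph, se_tree)
        assert len(kept) == 1


class TestDirectionalityFilter:
    @pytest.mark.parametrize(
        ("action", "directionality", "removed"),
        [
            ("antagonist", "LoF", True),
            ("agonist", "GoF", True),
            ("agonist", "LoF", False),
            ("antagonist", "GoF", False),
            ("antagonist", "unknown", False),
            ("", "LoF", False),
        ],
    )
    def test_contradiction_rule(self, action, directionality, removed):
        graph = SemanticGraph()
        chain(graph, "drug", "D1", action=action, directionality=directionality)
        mappings = find_mappings(graph)
        kept, dropped = filter_directionality(mappings, graph)
        assert bool(dropped) is removed
        assert len(kept) + len(dropped) == 1

    def test_unrecognized_action_kept_and_logged(self, caplog):
        graph = SemanticGraph()
        chain(graph, "drug", "D1", action="modulator of vibes", directionality="LoF")
        mappings = find_mappings(graph)
        with caplog.at_level("WARNING"):
            kept, _ = filter_directionality(mappings, graph)
        assert len(kept) == 1
        assert "modulator of vibes" in caplog.text


class TestAdmeFilter:
    def test_empty_list_is_identity_with_warning(self, caplog):
        graph = SemanticGraph()
        chain(graph, "drug", "D1", gene="CYP3A4")
        mappings = find_mappings(graph)
        with caplog.at_level("WARNING"):
            kept, removed = filter_adme(mappings, FilterConfig())
        assert kept == mappings and removed == []
        assert "no-op" in caplog.text

    def test_counts(self):
        graph = SemanticGraph()
        for i in range(10):
            gene = f"ADME{i}" if i < 3 else f"G{i}"
            chain(graph, f"drug{i}", f"D{i}", gene=gene)
        config = FilterConfig(adme_genes=frozenset({"ADME0", "ADME1", "ADME2"}))
        mappings = find_mappings(graph)
        kept, removed = filter_adme(mappings, config, graph)
        assert len(kept) == 7 and len(removed) == 3

    def test_case_insensitive_matching(self):
        graph = SemanticGraph()
        chain(graph, "drug", "D1", gene="cyp3a4")
        config = FilterConfig(adme_genes=frozenset({"CYP3A4"}))
        kept, removed = filter_adme(find_mappings(graph), config, graph)
        assert kept == [] and len(removed) == 1


def engineered_cascade(se_tree):
    """10 chains: 2 side-effect hits, 1 contradiction, 1 ADME, 6 clean."""
    graph = SemanticGraph()
    chain(graph, "d_se1", "D_child")
    add_side_effect(graph, "d_se1", "D_child")  # exact hit
    chain(graph, "d_se2", "D_parent")
    add_side_effect(graph, "d_se2", "D_child")  # one-node hit
    chain(graph, "d_contra", "D1", action="inhibitor", directionality="LoF")
    chain(graph, "d_adme", "D2", gene="CYP3A4")
    for i in range(6):
        chain(graph, f"d_clean{i}", f"DC{i}")
    config = FilterConfig(adme_genes=frozenset({"CYP3A4"}))
    return graph, find_mappings(graph), config


class TestCascade:
    def test_vacuous_filters_are_identity(self, se_tree):
        graph = SemanticGraph()
        for i in range(3):
            chain(graph, f"d{i}", f"D{i}")
        mappings = find_mappings(graph)
        result = run_cascade(
            mappings, graph, se_tree, FilterConfig(adme_genes=frozenset({"ZZZ"}))
        )
        assert list(result.kept) == mappings
        assert set(result.sequential_counts.values()) == {0}

    def test_engineered_counts(self, se_tree):
        graph, mappings, config = engineered_cascade(se_tree)
        assert len(mappings) == 10
        result = run_cascade(mappings, graph, se_tree, config)
        assert result.sequential_counts == {
            "side_effect": 2, "directionality": 1, "adme": 1,
        }
        assert len(result.kept) == 6

    def test_final_set_invariant_to_stage_order(self, se_tree):
        graph, mappings, base = engineered_cascade(se_tree)
        kept_sets = []
        for order in itertools.permutations(
            ("side_effect", "directionality", "adme")
        ):
            config = FilterConfig(adme_genes=base.adme_genes, stage_order=order)
            kept_sets.append(set(run_cascade(mappings, graph, se_tree, config).kept))
        assert all(s == kept_sets[0] for s in kept_sets)

    def test_filters_contractive_and_idempotent(self, se_tree):
        graph, mappings, config = engineered_cascade(se_tree)
        kept1, _ = filter_side_effects(mappings, graph, se_tree, config)
        kept2, removed2 = filter_side_effects(kept1, graph, se_tree, config)
        assert set(kept1) <= set(mappings)
        assert kept2 == kept1 and removed2 == []
        kept1, _ = filter_directionality(mappings, graph, config)
        kept2, removed2 = filter_directionality(kept1, graph, config)
        assert kept2 == kept1 and removed2 == []
        kept1, _ = filter_adme(mappings, config, graph)
        kept2, removed2 = filter_adme(kept1, config, graph)
        assert kept2 == kept1 and removed2 == []


class TestConfigIO:
    def test_action_sets_round_trip(self, tmp_path):
        path = tmp_path / "actions.yaml"
        save_action_sets(path)
        inhibitory, activating = load_action_sets(path)
        assert "antagonist" in inhibitory and "agonist" in activating
        assert not inhibitory & activating

    def test_adme_list_normalized_to_upper(self, tmp_path):
        path = tmp_path / "adme.txt"
        path.write_text("cyp3a4\n\nABCB1\n")
        assert load_adme_genes(path) == {"CYP3A4", "ABCB1"}

    def test_overlapping_action_sets_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(
                inhibitory_actions=frozenset({"agonist"}),
                activating_actions=frozenset({"agonist"}),
            )

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(equivalence_threshold=-0.2)
        with pytest.raises(ValueError):
            FilterConfig(equivalence_threshold=2.0)
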