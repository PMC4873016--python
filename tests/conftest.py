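from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from repograph.graph_model import (
    COMMON_DISEASE,
    GENE,
    PROTEIN,
    SMALL_MOLECULE,
    SemanticGraph,
)
from repograph.mesh_sim import MeshTree
from repograph.pipeline import PipelineConfig, run_all
from repograph.synthetic import FixtureSpec, generate

settings.register_profile(
    "repograph",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repograph")


@pytest.fixture()
def toy_tree() -> MeshTree:
    """Small two-branch forest covering the worked distance examples."""
    return MeshTree(
        {
            "D_root": ("nervous system diseases", ["C10"]),
            "D_parent": ("demyelinating diseases", ["C10.228"]),
            "D_child": ("multiple sclerosis", ["C10.228.140"]),
            "D_sibling": ("leukodystrophy", ["C10.228.200"]),
            "D_other": ("neoplasms", ["C04.100"]),
        }
    )


@pytest.fixture()
def deep_tree() -> MeshTree:
    """One area deep enough to reach a nine-node (Dist 10) separation."""
    entries = {}
    position = "C01"
    for level in range(11):
        entries[f"D_chain{level}"] = (f"chain {level}", [position])
        position += ".001"
    # a second branch, four levels deep, for cross-branch distances
    position = "C01"
    for level in range(1, 5):
        position += ".002"
        entries[f"D_branch{level}"] = (f"branch {level}", [position])
    return MeshTree(entries)


@pytest.fixture()
def chain_graph() -> SemanticGraph:
    """The minimal drug -> protein -> gene -> disease chain."""
    graph = SemanticGraph()
    graph.add_node("DB01", SMALL_MOLECULE, {"name": "drugA", "group": "approved"})
    graph.add_node("P01", PROTEIN)
    graph.add_node("G01", GENE, {"symbol": "G01"})
    graph.add_node("D000001", COMMON_DISEASE, {"mesh_ui": "D000001", "tree_numbers": "C01.001"})
    graph.add_edge("DB01", "P01", "binds_to", {"activity_nm": "100"})
    graph.add_edge("P01", "G01", "encoded_by")
    graph.add_edge("G01", "D000001", "involved_in", {"association_score": "0.9"})
    return graph


@dataclass(frozen=True)
class Bundle:
    input_dir: Path
    out_dir: Path
    truth: dict
    manifest: dict


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> Bundle:
    """The default synthetic bundle plus one full pipeline run over it."""
    root = tmp_path_factory.mktemp("bundle")
    input_dir = root / "in"
    out_dir = root / "out"
    truth = generate(FixtureSpec(seed=1), input_dir)
    manifest = run_all(input_dir, out_dir, PipelineConfig())
    return Bundle(input_dir, out_dir, truth, manifest)


def read_inferred(out_dir: Path) -> set[tuple[str, str]]:
    lines = (out_dir / "indications_inferred.tsv").read_text().splitlines()[1:]
    return {tuple(line.split("\t")[:2]) for line in lines}
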