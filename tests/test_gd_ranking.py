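import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from repograph.gd_ranking import (
    ContingencyCounts,
    GeneDiseasePair,
    RankingConfig,
    RankingError,
    SourceEvidence,
    ZeroCellError,
    contingency,
    lls_score,
    map_to_mesh,
    per_source_lls,
    score_all,
    select_gold_standard,
    tune_D,
    weighted_sum,
)

from _oracles import lls_oracle, ws_oracle


def pairs(*items):
    return frozenset(GeneDiseasePair(g, d) for g, d in items)


def make_source(source_id, pair_set, source_type="curated"):
    return SourceEvidence(source_id, source_type, pair_set)


class TestMapToMesh:
    def test_identity_mapping_returns_rows_unchanged(self):
        rows = [("G1", "D1", "unknown"), ("G2", "D2", "LoF")]
        evidence, report = map_to_mesh("s", "curated", rows, {"D1": {"D1"}, "D2": {"D2"}})
        assert evidence.pairs == pairs(("G1", "D1"), ("G2", "D2"))
        assert report.mapping_rate == 1.0

    def test_partial_mapping_rate(self):
        rows = [("G", f"MIM{i}", "unknown") for i in range(10)]
        mapping = {f"MIM{i}": {f"D{i}"} for i in range(7)}
        evidence, report = map_to_mesh("s", "curated", rows, mapping)
        assert len(evidence.pairs) == 7
        assert report.n_rows == 10 and report.n_mapped == 7
        assert report.mapping_rate == pytest.approx(0.7)

    def test_one_to_many_fans_out(self):
        evidence, _ = map_to_mesh(
            "s", "curated", [("G1", "MIM1", "unknown")], {"MIM1": {"D1", "D2"}}
        )
        assert evidence.pairs == pairs(("G1", "D1"), ("G1", "D2"))

    def test_zero_mapped_warns(self, caplog):
        with caplog.at_level("WARNING"):
            _, report = map_to_mesh("s", "curated", [("G1", "X", "unknown")], {})
        assert report.n_mapped == 0
        assert "0%" in caplog.text

    def test_output_deduplicated_on_gene_disease(self):
        rows = [("G1", "A", "LoF"), ("G1", "B", "GoF")]
        evidence, _ = map_to_mesh("s", "curated", rows, {"A": {"D1"}, "B": {"D1"}})
        assert len(evidence.pairs) == 1


class TestContingency:
    def test_source_equals_gold_equals_universe(self):
        p = pairs(*[("G", f"D{i}") for i in range(10)])
        counts = contingency(make_source("s", p), p, p)
        assert counts == ContingencyCounts(10, 0, 10, 0)

    def test_constructed_quadruple(self):
        universe = pairs(*[("G", f"D{i}") for i in range(100)])
        gold = pairs(*[("G", f"D{i}") for i in range(10)])
        source = pairs(*[("G", f"D{i}") for i in range(2, 22)])  # 8 gold, 12 not
        counts = contingency(make_source("s", source), gold, universe)
        assert counts == ContingencyCounts(8, 12, 10, 90)

    def test_disjoint_source_and_gold(self):
        universe = pairs(*[("G", f"D{i}") for i in range(30)])
        gold = pairs(*[("G", f"D{i}") for i in range(5)])
        source = pairs(*[("G", f"D{i}") for i in range(10, 20)])
        counts = contingency(make_source("s", source), gold, universe)
        assert counts == ContingencyCounts(0, 10, 5, 25)

    def test_empty_inputs_error(self):
        p = pairs(("G", "D1"))
        with pytest.raises(RankingError):
            contingency(make_source("s", frozenset()), p, p)
        with pytest.raises(RankingError):
            contingency(make_source("s", p), frozenset(), p)


class TestLLS:
    def test_null_enrichment_is_zero(self):
        assert lls_score(ContingencyCounts(1, 9, 10, 90)) == pytest.approx(0.0)

    def test_hand_arithmetic_ln6(self):
        assert lls_score(ContingencyCounts(8, 12, 10, 90)) == pytest.approx(math.log(6))

    def test_zero_cell_error_names_the_cell(self):
        with pytest.raises(ZeroCellError, match="neg_in_source"):
            lls_score(ContingencyCounts(10, 0, 10, 90))

    def test_pseudocount_policy_applies_half_to_all_cells(self):
        config = RankingConfig(zero_cell_policy="pseudocount")
        value = lls_score(ContingencyCounts(10, 0, 10, 90), config)
        assert value == pytest.approx(math.log((10.5 / 0.5) / (10.5 / 90.5)))

    @given(
        st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
    )
    def test_matches_arithmetic_oracle(self, a, b, c, d):
        counts = ContingencyCounts(a, b, c, d)
        assert lls_score(counts) == pytest.approx(lls_oracle(a, b, c, d), abs=1e-12)

    @given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200))
    def test_strictly_increasing_in_positive_support(self, pos, neg, gold):
        lo = lls_score(ContingencyCounts(pos, neg, gold, 1000))
        hi = lls_score(ContingencyCounts(pos + 1, neg, gold, 1000))
        assert hi > lo

    @given(st.integers(1, 50), st.integers(1, 50))
    def test_zero_exactly_when_odds_match_prior(self, k, m):
        # conditional odds k:m equal prior odds 10k:10m
        counts = ContingencyCounts(k, m, 10 * k, 10 * m)
        assert lls_score(counts) == pytest.approx(0.0, abs=1e-12)


class TestWeightedSum:
    @pytest.mark.parametrize(
        ("contributions", "D", "expected"),
        [
            ([0.5], 2.0, 0.5),
            ([16.57, 10.95], 5.0, 18.76),  # the two extreme published scores
            ([1.0, 1.0, 1.0], 5.0, 1.24),
        ],
    )
    def test_worked_examples(self, contributions, D, expected):
        assert weighted_sum(contributions, D) == pytest.approx(expected)

    def test_unsorted_input_is_an_error(self):
        with pytest.raises(RankingError, match="descending"):
            weighted_sum([1.0, 2.0], 5.0)

    def test_nonpositive_contribution_is_an_error(self):
        with pytest.raises(RankingError, match="> 0"):
            weighted_sum([1.0, -0.5], 5.0)

    def test_empty_is_an_error(self):
        with pytest.raises(RankingError, match="non-empty"):
            weighted_sum([], 5.0)

    @given(
        st.lists(st.floats(0.01, 50.0), min_size=1, max_size=8),
        st.floats(1.0, 10.0),
    )
    def test_matches_loop_oracle(self, values, D):
        contributions = sorted(values, reverse=True)
        assert weighted_sum(contributions, D) == pytest.approx(
            ws_oracle(contributions, D), abs=1e-12
        )

    @given(
        st.lists(st.floats(0.01, 50.0), min_size=1, max_size=8),
        st.floats(1.5, 10.0),
    )
    def test_bounded_by_geometric_series(self, values, D):
        contributions = sorted(values, reverse=True)
        ws = weighted_sum(contributions, D)
        c1 = contributions[0]
        assert c1 <= ws <= c1 * D / (D - 1) + 1e-9


class TestGoldSelection:
    def test_two_sources_forced_tie_breaks_lexicographically(self):
        universe = pairs(*[("G", f"D{i}") for i in range(40)])
        a = make_source("a", pairs(*[("G", f"D{i}") for i in range(10)]))
        b = make_source("b", pairs(*[("G", f"D{i}") for i in range(5, 25)]))
        selection = select_gold_standard([b, a])
        assert selection.source_id == "a"
        assert selection.average_ranks == {"a": 1.0, "b": 1.0}

    def test_three_source_fixture_recovers_designed_winner(self):
        # a overlaps heavily with both b and c, while b and c barely overlap,
        # so a ranks first in both rounds where it is a test source (average
        # rank 1.0); b and c average 1.75 each (verified by hand over the
        # 3 x 2 contingency table).
        base = [("G", f"D{i}") for i in range(20)]
        a = make_source("a", pairs(*base))
        b = make_source("b", pairs(*base[:14], *[("H", f"D{i}") for i in range(12)]))
        c = make_source("c", pairs(*base[6:], *[("K", f"D{i}") for i in range(12)]))
        selection = select_gold_standard([a, b, c])
        assert selection.source_id == "a"
        assert selection.average_ranks["a"] == 1.0
        assert selection.average_ranks["a"] == min(selection.average_ranks.values())

    def test_identical_sources_tie(self):
        p = pairs(*[("G", f"D{i}") for i in range(10)])
        config = RankingConfig(zero_cell_policy="pseudocount")
        selection = select_gold_standard(
            [make_source("y", p), make_source("x", p), make_source("z", p)], config
        )
        assert selection.source_id == "x"

    def test_needs_two_sources(self):
        with pytest.raises(RankingError):
            select_gold_standard([make_source("a", pairs(("G", "D1")))])


def three_source_fixture():
    """Gold-quality source plus two weaker ones over a shared universe."""
    genes = [f"G{i}" for i in range(30)]
    diseases = [f"D{i}" for i in range(30)]
    gold = {(genes[i % 30], diseases[(i * 7) % 30]) for i in range(60)}
    def sample(reliability, n_noise, seed):
        local = np.random.default_rng(seed)
        kept = {p for p in gold if local.random() < reliability}
        while len(kept) < len(gold) * reliability + n_noise - 2:
            p = (genes[local.integers(30)], diseases[local.integers(30)])
            if p not in gold:
                kept.add(p)
        return pairs(*kept)
    return [
        make_source("strong", sample(0.9, 25, 1)),
        make_source("medium", sample(0.6, 25, 2)),
        make_source("weak", sample(0.3, 25, 3)),
    ]


class TestScoreAll:
    def test_single_source_degenerates_with_warning(self, caplog):
        # one source: every pair's WS equals that source's LLS, so the
        # min-max normalization collapses and every score becomes 1.0
        gold = make_source("gold", pairs(*[(f"G{i}", f"D{i}") for i in range(10)]))
        with caplog.at_level("WARNING"):
            flat = score_all([gold], "gold", RankingConfig(universe="cartesian"))
        assert len(flat) == 10
        assert all(s.association_score == 1.0 for s in flat)
        assert "degenerate WS range" in caplog.text

    def test_ws_equals_weighted_sum_of_member_source_lls(self):
        sources = three_source_fixture()
        config = RankingConfig(universe="cartesian")
        lls = per_source_lls(sources, "strong", config)
        scored = score_all(sources, "strong", config)
        by_pair = {(s.gene, s.disease): s for s in scored}
        for source in sources:
            assert lls[source.source_id] > 0
        for (gene, disease), assoc in by_pair.items():
            member_lls = sorted(
                (
                    lls[s.source_id]
                    for s in sources
                    if GeneDiseasePair(gene, disease) in s.pairs
                ),
                reverse=True,
            )
            assert assoc.ws == pytest.approx(weighted_sum(member_lls, 5.0), abs=1e-12)

    def test_normalization_is_min_max_and_rank_preserving(self):
        sources = three_source_fixture()
        scored = score_all(sources, "strong", RankingConfig(universe="cartesian"))
        ws = [s.ws for s in scored]
        norm = [s.association_score for s in scored]
        lo, hi = min(ws), max(ws)
        for w, n in zip(ws, norm):
            assert n == pytest.approx((w - lo) / (hi - lo))
        rho = spearmanr(ws, norm).statistic
        assert rho == pytest.approx(1.0)

    def test_directionality_consensus(self):
        gold = make_source(
            "gold",
            frozenset(
                [GeneDiseasePair("G1", "D1", "LoF"), GeneDiseasePair("G2", "D2", "LoF")]
            ),
        )
        agree = make_source(
            "agree",
            frozenset(
                [
                    GeneDiseasePair("G1", "D1", "LoF"),
                    GeneDiseasePair("G2", "D2", "GoF"),
                    GeneDiseasePair("G3", "D3"),  # keeps the contingency non-degenerate
                ]
            ),
        )
        scored = score_all([gold, agree], "gold", RankingConfig(universe="cartesian"))
        by_pair = {(s.gene, s.disease): s.directionality for s in scored}
        assert by_pair[("G1", "D1")] == "LoF"  # agreement
        assert by_pair[("G2", "D2")] == "unknown"  # conflict -> conservative


class TestTuneD:
    def test_noisy_copy_of_gold_gives_auc_above_half(self):
        sources = three_source_fixture()
        result = tune_D(sources, "strong", config=RankingConfig(universe="cartesian"))
        assert all(auc > 0.5 for auc in result.auc_by_D.values())

    def test_single_source_is_d_invariant_and_returns_smallest(self):
        sources = three_source_fixture()[:2]
        result = tune_D(
            sources, "strong", candidate_Ds=[2.0, 5.0, 8.0],
            config=RankingConfig(universe="cartesian"),
        )
        aucs = set(round(a, 12) for a in result.auc_by_D.values())
        assert len(aucs) == 1
        assert result.best_D == 2.0

    def test_all_positive_labels_error(self):
        gold = make_source("gold", pairs(*[(f"G{i}", f"D{i}") for i in range(10)]))
        subset = make_source("sub", pairs(*[(f"G{i}", f"D{i}") for i in range(5)]))
        config = RankingConfig(zero_cell_policy="pseudocount", universe="cartesian")
        with pytest.raises(RankingError, match="both positive and negative"):
            tune_D([gold, subset], "gold", config=config)


def test_config_validation():
    with pytest.raises(RankingError):
        RankingConfig(D=0.5)
    with pytest.raises(RankingError):
        RankingConfig(zero_cell_policy="ignore")
    with pytest.raises(RankingError):
        RankingConfig(universe="everything")
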