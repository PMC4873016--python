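"""Evidence integration and Bayesian ranking of gene--disease associations.

Each evidence source (curated database, experimental catalogue, literature
mining, cross-species prediction) contributes a set of gene--disease pairs.
A gold-standard source is chosen by round-robin benchmarking, every source
is scored by a log-likelihood score (LLS)

    LLS = log[ (P(L|E) / notP(L|E)) / (P(L) / notP(L)) ]

estimated from the contingency of the source's pairs against the gold
standard over the captured pair universe, and per-association confidences
are combined by the weighted sum

    WS = sum_i C_i / D**(i-1)

with contributions sorted descending so lower-confidence evidence is
progressively down-weighted by the divisor D (default 5.0).  WS values are
min--max normalized to the [0, 1] association score carried on
``involved_in`` edges.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

SOURCE_TYPES = frozenset({"curated", "experimental", "literature", "predicted"})
DIRECTIONALITIES = frozenset({"LoF", "GoF", "unknown"})

ZERO_CELL_ERROR = "error"
ZERO_CELL_PSEUDOCOUNT = "pseudocount"
UNIVERSE_CAPTURED = "captured"
UNIVERSE_CARTESIAN = "cartesian"


class RankingError(ValueError):
    """Degenerate input to the ranking computation."""


class ZeroCellError(RankingError):
    """A contingency cell is zero under the strict policy."""


@dataclass(frozen=True)
class GeneDiseasePair:
    """A gene--disease association; identity is on (gene, disease) only."""

    gene: str
    disease: str
    directionality: str = field(default="unknown", compare=False)

    def __post_init__(self) -> None:
        if not self.gene or not self.disease:
            raise RankingError("gene and disease must be non-empty")
        if self.directionality not in DIRECTIONALITIES:
            raise RankingError(f"unknown directionality {self.directionality!r}")


@dataclass(frozen=True)
class SourceEvidence:
    """One source's deduplicated pair set."""

    source_id: str
    source_type: str
    pairs: frozenset[GeneDiseasePair]

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise RankingError(f"unknown source type {self.source_type!r}")


@dataclass(frozen=True)
class ContingencyCounts:
    """The count quadruple behind the LLS.

    ``pos_in_source`` / ``neg_in_source`` are the source's pairs inside /
    outside the gold standard; ``pos_total`` / ``neg_total`` are the gold
    and non-gold pair counts over the universe.
    """

    pos_in_source: int
    neg_in_source: int
    pos_total: int
    neg_total: int

    def __post_init__(self) -> None:
        for name in ("pos_in_source", "neg_in_source", "pos_total", "neg_total"):
            if getattr(self, name) < 0:
                raise RankingError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RankingConfig:
    D: float = 5.0
    zero_cell_policy: str = ZERO_CELL_ERROR
    universe: str = UNIVERSE_CAPTURED

    def __post_init__(self) -> None:
        if self.D < 1:
            raise RankingError(f"D must be >= 1, got {self.D}")
        if self.zero_cell_policy not in (ZERO_CELL_ERROR, ZERO_CELL_PSEUDOCOUNT):
            raise RankingError(f"unknown zero-cell policy {self.zero_cell_policy!r}")
        if self.universe not in (UNIVERSE_CAPTURED, UNIVERSE_CARTESIAN):
            raise RankingError(f"unknown universe mode {self.universe!r}")


@dataclass(frozen=True)
class ScoredAssociation:
    """One pair with its per-source contributions and integrated score."""

    gene: str
    disease: str
    contributions: tuple[float, ...]
    ws: float
    association_score: float
    directionality: str

    @property
    def n_sources(self) -> int:
        return len(self.contributions)


@dataclass(frozen=True)
class MappingReport:
    n_rows: int
    n_mapped: int

    @property
    def mapping_rate(self) -> float:
        return self.n_mapped / self.n_rows if self.n_rows else 0.0


# -- identifier mapping -----------------------------------------------------


def map_to_mesh(
    source_id: str,
    source_type: str,
    rows: Iterable[tuple[str, str, str]],
    mapping: Mapping[str, Iterable[str]],
) -> tuple[SourceEvidence, MappingReport]:
    """Expand foreign-keyed evidence rows to MeSH-keyed pairs.

    ``rows`` are ``(gene_symbol, foreign_id, directionality)`` triples keyed
    by MIM numbers or UMLS CUIs; ``mapping`` sends each foreign id to one or
    more MeSH UIs (many-to-many expansion).  Rows already keyed by MeSH pass
    through an identity mapping unchanged.  Unmapped rows are counted and
    the output deduplicated on (gene, disease).
    """
    pairs: dict[tuple[str, str], GeneDiseasePair] = {}
    n_rows = 0
    n_mapped = 0
    for gene, foreign_id, directionality in rows:
        n_rows += 1
        targets = sorted(set(mapping.get(foreign_id, ())))
        if not targets:
            continue
        n_mapped += 1
        for ui in targets:
            pairs.setdefault(
                (gene, ui), GeneDiseasePair(gene, ui, directionality or "unknown")
            )
    if n_rows and not n_mapped:
        log.warning("source %s: 0%% of %d rows mapped to MeSH", source_id, n_rows)
    evidence = SourceEvidence(source_id, source_type, frozenset(pairs.values()))
    return evidence, MappingReport(n_rows, n_mapped)


# -- LLS --------------------------------------------------------------------


def contingency(
    source: SourceEvidence,
    gold: frozenset[GeneDiseasePair] | set[GeneDiseasePair],
    universe: frozenset[GeneDiseasePair] | set[GeneDiseasePair],
) -> ContingencyCounts:
    """Exact set arithmetic on (gene, disease) identity."""
    if not source.pairs:
        raise RankingError(f"source {source.source_id} has no pairs")
    if not gold:
        raise RankingError("gold standard is empty")
    pos_in = len(source.pairs & set(gold))
    return ContingencyCounts(
        pos_in_source=pos_in,
        neg_in_source=len(source.pairs) - pos_in,
        pos_total=len(gold),
        neg_total=len(universe) - len(set(gold) & set(universe)),
    )


def lls_score(counts: ContingencyCounts, config: RankingConfig = RankingConfig()) -> float:
    """Natural-log LLS of one source against the gold standard.

    Under the pseudocount policy a +0.5 continuity correction is applied to
    all four cells whenever any cell is zero; under the strict policy a zero
    cell raises, naming the offending cell.
    """
    cells = {
        "pos_in_source": counts.pos_in_source,
        "neg_in_source": counts.neg_in_source,
        "pos_total": counts.pos_total,
        "neg_total": counts.neg_total,
    }
    zero = [name for name, value in cells.items() if value == 0]
    values = dict(cells)
    if zero:
        if config.zero_cell_policy == ZERO_CELL_ERROR:
            raise ZeroCellError(f"zero count in cell(s): {', '.join(zero)}")
        values = {name: value + 0.5 for name, value in cells.items()}
    conditional = values["pos_in_source"] / values["neg_in_source"]
    prior = values["pos_total"] / values["neg_total"]
    return math.log(conditional / prior)


def captured_universe(sources: Sequence[SourceEvidence]) -> frozenset[GeneDiseasePair]:
    out: set[GeneDiseasePair] = set()
    for source in sources:
        out |= source.pairs
    return frozenset(out)


def _universe(sources: Sequence[SourceEvidence], config: RankingConfig) -> frozenset[GeneDiseasePair]:
    captured = captured_universe(sources)
    if config.universe == UNIVERSE_CAPTURED:
        return captured
    genes = sorted({p.gene for p in captured})
    diseases = sorted({p.disease for p in captured})
    return frozenset(
        GeneDiseasePair(g, d) for g, d in itertools.product(genes, diseases)
    )


@dataclass(frozen=True)
class GoldSelection:
    source_id: str
    average_ranks: Mapping[str, float]
    lls_table: Mapping[str, Mapping[str, float]]  # gold -> test -> LLS


def select_gold_standard(
    sources: Sequence[SourceEvidence], config: RankingConfig = RankingConfig()
) -> GoldSelection:
    """Round-robin benchmarking: the source with the best average rank wins.

    Every source takes a turn as the gold standard; all other sources are
    LLS-scored against it and ranked (rank 1 = highest LLS, ties get the
    average rank).  Each source's ranks are averaged over the rounds in
    which it was a test source, and the minimum average rank wins; ties
    break by lexicographic source id (logged).  Rounds where scoring is
    degenerate (a zero cell under the strict policy) are skipped with a
    warning.
    """
    if len(sources) < 2:
        raise RankingError("gold-standard selection needs >= 2 sources")
    universe = _universe(sources, config)
    lls_table: dict[str, dict[str, float]] = {}
    ranks: dict[str, list[float]] = {s.source_id: [] for s in sources}
    for gold_source in sources:
        round_scores: dict[str, float] = {}
        for test_source in sources:
            if test_source.source_id == gold_source.source_id:
                continue
            try:
                counts = contingency(test_source, gold_source.pairs, universe)
                round_scores[test_source.source_id] = lls_score(counts, config)
            except RankingError as exc:
                log.warning(
                    "gold=%s test=%s: degenerate round skipped (%s)",
                    gold_source.source_id, test_source.source_id, exc,
                )
        if not round_scores:
            continue
        lls_table[gold_source.source_id] = round_scores
        ordered = sorted(round_scores)
        scores = np.array([round_scores[sid] for sid in ordered])
        round_ranks = rankdata(-scores, method="average")
        for sid, rank in zip(ordered, round_ranks):
            ranks[sid].append(float(rank))
    averages = {
        sid: (sum(values) / len(values)) for sid, values in ranks.items() if values
    }
    if not averages:
        raise RankingError("every benchmarking round was degenerate")
    best = min(averages.values())
    winners = sorted(sid for sid, avg in averages.items() if avg == best)
    if len(winners) > 1:
        log.info("gold-standard tie between %s; choosing %s", winners, winners[0])
    return GoldSelection(winners[0], averages, lls_table)


# -- weighted sum -----------------------------------------------------------


def weighted_sum(contributions: Sequence[float], D: float) -> float:
    """Eq-2 integration: WS = sum_i C_i / D**(i-1).

    ``contributions`` must be sorted descending and strictly positive
    (sorting is the caller's declared responsibility and is verified here);
    D must be >= 1.
    """
    if not contributions:
        raise RankingError("contributions must be non-empty")
    if D < 1:
        raise RankingError(f"D must be >= 1, got {D}")
    if any(c <= 0 for c in contributions):
        raise RankingError("all contributions must be > 0")
    if any(a < b for a, b in zip(contributions, contributions[1:])):
        raise RankingError("contributions must be sorted descending")
    return float(sum(c / D**i for i, c in enumerate(contributions)))


def per_source_lls(
    sources: Sequence[SourceEvidence],
    gold_id: str,
    config: RankingConfig = RankingConfig(),
) -> dict[str, float]:
    """LLS of every source against the chosen gold source's pairs.

    The gold source's own contingency against itself always has a zero
    negative cell (its pairs are the gold), so its LLS is computed under
    the +0.5 continuity correction regardless of the configured policy;
    this keeps the gold source's pairs scoreable.
    """
    by_id = {s.source_id: s for s in sources}
    if gold_id not in by_id:
        raise RankingError(f"unknown gold source {gold_id!r}")
    gold = by_id[gold_id].pairs
    universe = _universe(sources, config)
    scores: dict[str, float] = {}
    for source in sources:
        counts = contingency(source, gold, universe)
        if source.source_id == gold_id:
            relaxed = RankingConfig(config.D, ZERO_CELL_PSEUDOCOUNT, config.universe)
            scores[source.source_id] = lls_score(counts, relaxed)
        else:
            scores[source.source_id] = lls_score(counts, config)
    return scores


def _consensus_directionality(annotations: Iterable[str]) -> str:
    seen = {a for a in annotations if a != "unknown"}
    return seen.pop() if len(seen) == 1 else "unknown"


def score_all(
    sources: Sequence[SourceEvidence],
    gold_id: str,
    config: RankingConfig = RankingConfig(),
) -> list[ScoredAssociation]:
    """Score every pair in the captured universe by WS + min--max normalization.

    Sources with LLS <= 0 carry no usable evidence weight and are excluded
    from the contributions (their count is logged); pairs supported only by
    such sources are dropped.  The consensus directionality is LoF/GoF when
    the contributing sources agree and ``unknown`` otherwise.  When all WS
    values coincide the normalized score degenerates to 1.0 for every pair
    (logged as a warning).
    """
    lls_by_source = per_source_lls(sources, gold_id, config)
    positive = [s for s in sources if lls_by_source[s.source_id] > 0]
    dropped_sources = [s.source_id for s in sources if lls_by_source[s.source_id] <= 0]
    if dropped_sources:
        log.warning("sources with non-positive LLS excluded from WS: %s", dropped_sources)
    support: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for source in positive:
        lls = lls_by_source[source.source_id]
        for pair in source.pairs:
            support.setdefault((pair.gene, pair.disease), []).append(
                (lls, pair.directionality)
            )
    n_unscored = len(captured_universe(list(sources))) - len(support)
    if n_unscored:
        log.info("%d pair(s) lack positively-scored support and were dropped", n_unscored)
    scored: list[tuple[str, str, tuple[float, ...], float, str]] = []
    for (gene, disease), entries in support.items():
        contributions = tuple(sorted((lls for lls, _ in entries), reverse=True))
        ws = weighted_sum(contributions, config.D)
        directionality = _consensus_directionality(d for _, d in entries)
        scored.append((gene, disease, contributions, ws, directionality))
    if not scored:
        raise RankingError("no pair could be scored")
    ws_values = [item[3] for item in scored]
    lo, hi = min(ws_values), max(ws_values)
    if hi == lo:
        log.warning("degenerate WS range (%g); all association scores set to 1.0", hi)
    out = [
        ScoredAssociation(
            gene,
            disease,
            contributions,
            ws,
            1.0 if hi == lo else (ws - lo) / (hi - lo),
            directionality,
        )
        for gene, disease, contributions, ws, directionality in scored
    ]
    out.sort(key=lambda a: (-a.ws, a.gene, a.disease))
    return out


# -- D tuning ---------------------------------------------------------------


@dataclass(frozen=True)
class TuneResult:
    best_D: float
    auc_by_D: Mapping[float, float]


def tune_D(
    sources: Sequence[SourceEvidence],
    gold_id: str,
    candidate_Ds: Sequence[float] | None = None,
    config: RankingConfig = RankingConfig(),
) -> TuneResult:
    """Grid-search D by ROC AUC against the gold label set.

    The gold source is held out of the scoring inputs but provides the
    positive labels: every pair captured by the remaining sources is scored
    by WS, labelled positive iff it is in the gold pair set, and the AUC of
    the WS ranking computed.  Returns the argmax-AUC D (ties go to the
    smaller D).  The default grid is 1.0--8.0 in steps of 0.5.
    """
    if candidate_Ds is None:
        candidate_Ds = [1.0 + 0.5 * i for i in range(15)]
    if not candidate_Ds:
        raise RankingError("candidate grid must be non-empty")
    by_id = {s.source_id: s for s in sources}
    if gold_id not in by_id:
        raise RankingError(f"unknown gold source {gold_id!r}")
    gold_pairs = by_id[gold_id].pairs
    rest = [s for s in sources if s.source_id != gold_id]
    if not rest:
        raise RankingError("tune_D needs at least one non-gold source")
    universe = _universe(rest, config)
    lls_by_source = {}
    for source in rest:
        counts = contingency(source, gold_pairs, universe)
        lls_by_source[source.source_id] = lls_score(counts, config)
    positive = [s for s in rest if lls_by_source[s.source_id] > 0]
    if not positive:
        raise RankingError("no non-gold source has positive LLS")
    support: dict[GeneDiseasePair, list[float]] = {}
    for source in positive:
        for pair in source.pairs:
            support.setdefault(pair, []).append(lls_by_source[source.source_id])
    pairs = sorted(support, key=lambda p: (p.gene, p.disease))
    labels = np.array([1 if pair in gold_pairs else 0 for pair in pairs])
    if labels.min() == labels.max():
        raise RankingError("tune_D needs both positive and negative pairs")
    contributions = [tuple(sorted(support[p], reverse=True)) for p in pairs]
    auc_by_D: dict[float, float] = {}
    best_D: float | None = None
    best_auc = -math.inf
    for D in sorted(candidate_Ds):
        ws = np.array([weighted_sum(c, D) for c in contributions])
        auc = float(roc_auc_score(labels, ws))
        auc_by_D[D] = auc
        if auc > best_auc:
            best_auc = auc
            best_D = D
    assert best_D is not None
    return TuneResult(best_D, auc_by_D)
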