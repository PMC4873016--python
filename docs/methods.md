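# Methods

This note documents the models implemented in `repograph`, the defaults
chosen where the design was genuinely open, and what the synthetic
fixtures do and do not show about real data.

## Evidence model and the LLS

Each evidence source is reduced to a deduplicated set of (gene symbol,
MeSH UI) pairs; directionality (LoF / GoF / unknown) is carried as an
annotation and never participates in pair identity. Identifier mapping
(MIM or UMLS CUI → MeSH) is a many-to-many expansion applied before
deduplication; unmapped rows are counted and dropped.

The log-likelihood score of a source against a gold standard is

    LLS = ln[(pos_in/neg_in) / (pos_total/neg_total)]

from the contingency quadruple (source pairs inside/outside the gold,
gold/non-gold pairs over the universe).

**Choice of universe.** Two priors are supported: `captured` (the union
of all source pair sets) and `cartesian` (every combination of the
captured genes and diseases). The pipeline default is `cartesian`. The
reasoning: published per-source LLS values for this class of integration
sit in the 11–17 range in natural log, i.e. conditional-to-prior odds
ratios of 10⁵–10⁷, which are only reachable when the prior is computed
over the full gene × disease combination space (hundreds of millions of
cells for realistic vocabularies); a captured-pairs prior on toy data
makes the gold source a large fraction of the universe and drives most
LLS values negative. LLS *ordering* across sources is identical under
both priors (the prior is a shared constant), so benchmarking and
gold-standard selection are unaffected by this choice.

**Zero cells.** The strict policy (default at the library level) raises
and names the zero cell; the `pseudocount` policy adds +0.5 to all four
cells. One systematic exception: the gold source scored against itself
always has `neg_in = 0` by construction, so its own LLS is computed
under the continuity correction regardless of policy. This keeps pairs
supported only by the gold source scoreable, at the price of an
extrapolated (large but finite) confidence for them.

**Gold-standard selection** is a round robin: each source takes a turn
as gold, all others are scored and ranked (ties get average ranks), and
the best average rank wins, ties breaking lexicographically. Degenerate
rounds are skipped with a warning rather than failing the selection.

## Weighted-sum integration

WS = Σ Cᵢ / D^(i−1) over the descending per-source LLS contributions of
a pair. D models inter-source dependence (curated sources seed each
other); D = 5.0 is the default operating point and `tune_D` grid-searches
1.0–8.0 by ROC AUC with the gold source held out as the label set.
D = 1 (no down-weighting) is accepted: it is a legal grid point and WS
is well defined there. Sources with LLS ≤ 0 contribute no usable
evidence weight and are excluded; pairs supported only by such sources
are dropped with a logged count rather than given a meaningless score.
WS is min–max normalized over the scored set to give the [0, 1]
association score: rank-preserving (Spearman ρ = 1 with WS), bounded,
and degenerate ranges (all WS equal) collapse to 1.0 with a warning.
Directionality is a conservative consensus: LoF or GoF only when all
annotating sources agree, otherwise unknown — a wrong LoF/GoF would
wrongly trigger the contradiction filter downstream.

## Semantic similarity

Sim(a, b) = 1 − log Dist / log(2·depth), clamped to [0, 1], with
Dist counted in nodes over the MeSH tree-number forest (identical
concept = 1, parent–child = 2) and depth = 10. The log base cancels
algebraically. The parameterization is over-determined by the three
conventionally quoted thresholds — 0.768 (one node), 0.633 (two nodes),
0.231 (nine nodes) — and (depth 10, node-count) is the unique
combination reproducing all three; both parameters remain configurable.
Distances are minimized over all tree-number pairs of the two diseases
(synonymous placements in multiple branches), and pairs sharing no
prefix score 0: no virtual root joins the top-level categories, since a
virtual root would make all diseases weakly similar and pollute the
side-effect filter. Printed-precision comparisons use truncation (not
rounding) to three decimals.

## Area scores

A disease belongs to every top-level code prefixing one of its tree
numbers (duplication intended, matching how area totals are reported).
TAU = (1 − P(Dr-D)) · P(G-D) · f(|ta|). The size factor is genuinely
ambiguous in the source material; the prose contract (small areas
suppressed, the largest knowledge-rich undrugged area scoring
(1 − P(Dr-D))·P(G-D)) forces a factor increasing in |ta| equal to 1 at
the maximum, so the default is f = |ta|/MAX; the literal decreasing
reading (1 − |ta|/MAX) and 1 − 1/(MAX·|ta|) are available via
`size_factor_mode` for sensitivity analysis. Eligibility uses a strict
share threshold of 1/n_areas over membership counts with duplication;
n_areas defaults to the number of observed areas (29 for the full MeSH
disease forest, giving the 3.44 % rule).

## Mining, scoring, deduplication

The matcher is specialized to the four-node pattern (approved drug →
protein → gene → disease) and enumerates exhaustively; parallel
binds_to edges (multiple activity measurements, or measurements from
different databases) each yield a mapping, and deduplication later
resolves to the best-scoring path. Activities in nM are normalized as
1 − 0.1·log₁₀(v), clamped to [0, 1] (1 nM → 1.0, 100 nM → 0.8,
≥ 10¹⁰ nM → 0); an edge with no measured activity receives the
normalized constant 0.8 directly — 0.8 is read as a value on the
normalized scale, sitting at the 100 nM equivalent so unmeasured
interactions are neither discarded nor over-weighted. Output ordering is
fully specified (drug, disease, −score, edge ids) so runs are
byte-for-byte reproducible.

## Filter cascade

Stages: side-effect similarity (drop a mapping whose drug has a recorded
side effect on the same disease node or any disease with Sim ≥ ET,
default ET = 0.768; rare diseases without a MeSH UI match exactly only),
mechanism contradiction (inhibitory action × LoF, or activating action ×
GoF; anything missing or unrecognized is kept, unrecognized terms are
logged for triage), and ADME genes (case-insensitive symbol match).
The action-term classification is shipped as an editable `actions.yaml`
because the inferred-contradiction count is sensitive to it. Every
predicate depends only on the mapping itself, so the final kept set is
stage-order invariant; per-stage counts are order-dependent and are
therefore reported under both sequential and independent accounting.

## Validation

A known (drug, disease) is identified when a same-drug inference lands
on the same disease node (always a match, at any threshold) or within
Sim ≥ threshold (default 0.633). Knowns whose drug produced no mapping
at all cannot be recovered and are excluded from the recall denominator
(both counts are reported). The ROC labels each inferred indication
positive iff it matches some known at the threshold and ranks by mapping
score; AUC is the midrank Mann–Whitney statistic. This labeling is the
only one constructible from the pipeline's own outputs; it measures how
well the score orders rediscovered knowns ahead of novel hypotheses, not
clinical truth.

## Synthetic fixtures

The generator emulates the statistical *shape* of the real inputs, not
their scale: a three-area MeSH forest of complete binary trees five
levels deep (189 diseases, a 5 % multi-area fraction), 120 genes, a
200-pair gold standard, and three sources with reliabilities 0.9 / 0.6 /
0.3 (probability of containing a gold pair) diluted with 30 % noise
pairs; the most reliable source is emitted keyed by MIM ids with its
mapping table to exercise identifier mapping end-to-end. Thirty random
drugs with two targets each carry log-uniform activities over 1–10⁶ nM
(20 % unmeasured). Planted structure — five clean indication chains (one
routed through a rare disease with a MeSH synonym), side-effect traps at
node distances 1/2/3, one contradiction, one ADME route, and known
indications at node distances 1/2/3/10 — makes every pipeline stage's
behaviour directly assertable against the emitted `truth.json`.

All sampling runs off a single seeded `numpy` generator and outputs are
written in sorted order, so a spec is byte-reproducible. What passing
tests show: the machinery is correct at these conditions (exhaustive
search, threshold semantics, ordering recovery). What they do not show:
performance at realistic scale (10⁵–10⁶ pairs and mappings), robustness
to real vocabulary irregularities (missing tree numbers, many-to-many
synonymy at scale), or the biological validity of inferred indications.

## Numerical and degenerate-input conventions

Natural logarithms throughout (the Sim base cancels; the LLS base is a
convention and only rescales scores). Attribute values round-trip as
text; floats are formatted with fixed precision in all outputs so reruns
are byte-identical, and the run manifest carries no timestamps. Ties are
always broken lexicographically and logged. Empty gold standards, empty
sources, single-class ROC labelings and zero-cell contingencies raise
named errors rather than returning silent defaults.

## Known limitations

- The in-memory graph targets toy-to-moderate scale; there is no
  persistent graph-database backend (GraphML export is provided).
- Only the four-node pattern is mined; there is no general pattern
  language.
- The validation AUC depends on the Sim-threshold labeling above and is
  not comparable across thresholds.
- No burden-of-disease weighting, target cellular-location or
  permeability filtering; directionality coverage is whatever the
  evidence tables annotate.
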