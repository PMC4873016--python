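# repograph

Systematic, data-driven drug repositioning from gene–disease evidence.

`repograph` is for computational drug-discovery researchers who want to
(1) integrate heterogeneous gene–disease (G–D) association sources into a
single ranked list, (2) assemble a typed semantic network of drugs,
protein targets, genes and diseases, (3) find therapeutic areas with
unmet need, (4) mine the network exhaustively for target-based
repositioning hypotheses, and (5) prune and validate those hypotheses.
Everything runs at toy scale out of the box via a deterministic
synthetic-fixture generator, so the whole pipeline is testable without
any database downloads.

## The method

**Evidence integration.** Each source *E* (curated database, GWAS
catalogue, literature mining, animal-model predictions) contributes a set
of (gene, disease) pairs keyed by MeSH. A gold-standard source is chosen
by round-robin benchmarking, and every source receives a log-likelihood
score against it,

```
LLS(E) = ln [ (P(L|E) / ¬P(L|E)) / (P(L) / ¬P(L)) ]
```

where the conditional odds come from the source's contingency with the
gold standard and the prior odds from the pair universe. Per-association
confidences C₁ ≥ C₂ ≥ … are combined by the weighted sum

```
WS = Σᵢ Cᵢ / D^(i-1)        (D = 5.0 by default)
```

so correlated lower-confidence evidence is progressively down-weighted;
WS is min–max normalized to the [0, 1] *association score*.

**Semantic distance.** Disease similarity follows a Leacock–Chodorow
path measure over MeSH tree numbers,

```
Sim(a, b) = 1 − log Dist(a, b) / log(2·depth)
```

with node-count distances (identical = 1, parent–child = 2) and
hierarchy depth 10. This calibration yields the working thresholds
Sim = 0.768 (one node away), 0.633 (two nodes) and 0.231 (nine nodes).

**Area prioritization.** For each top-level MeSH code,
`TAU = (1 − P(Dr-D)) · P(G-D) · |ta|/MAX` scores unmet need (large,
genetically characterized, under-drugged areas score high) and
`RTA = P(Dr-D) · P(G-D)` scores knowledge richness; areas holding
≤ 1/n_areas of all disease memberships are flagged ineligible.

**Mining and filtering.** All instances of the four-node pattern
`drug → binds_to → protein → encoded_by → gene → involved_in → disease`
over approved small molecules are enumerated and scored by
`(⋄activity + association score) / 2`, where binding activities in nM
are normalized as `1 − 0.1·log₁₀(nM)` (missing measurements count 0.8).
Mappings are then pruned in three stages — side-effect similarity
(Sim ≥ 0.768 to a known side effect of the same drug), drug-mechanism /
directionality contradictions (e.g. an inhibitor against a
loss-of-function association), and ADME-gene routes — deduplicated to
the best mapping per (drug, disease), and validated against known
indications at Sim ≥ 0.633 (recall over recoverable knowns, plus ROC
AUC of the score ranking).

## Worked example

```
$ repograph fixture --seed 7 --out fixture/
fixture: 214 gold pairs, 5 planted indications -> fixture/

$ repograph run-all -i fixture/ -o run/
run-all: 176 mappings -> 157 indications, recall 0.312
```

The fixture plants five full drug→protein→gene→disease support chains,
three side-effect traps at node distances 1–3, one mechanism
contradiction and one ADME route. In `run/manifest.json` the three
sources score LLS 10.65 / 5.16 / 4.28 — recovering their designed
reliabilities 0.9 / 0.6 / 0.3 — and the filter cascade removes
5 + 7 + 5 mappings (side effect, directionality, ADME). The top
inferred indications are exactly the planted chains:

```
$ head -4 run/indications_inferred.tsv
drug    disease      score     via_protein  via_gene
PDRG001 ORDO:000001  0.988710  PPRT001      PGEN001
PDRG002 D000033      0.988710  PPRT002      PGEN002
PDRG003 D000034      0.988710  PPRT003      PGEN003
```

(the first routes through a rare disease that was merged with its
synonymous MeSH term). Validation against the bundled known indications
reports `recall 0.312 (5/16), AUC 0.697`: the knowns planted at node
distances 1–3 are recovered at the 0.633 threshold, the one nine nodes
away deliberately is not. Area scores land in `run/areas.tsv`:

```
ta   n_diseases  p_gd      p_drd     tau       rta       eligible
C01  64          0.984375  0.140625  0.845947  0.138428  true
```

## Layout

- `repograph.graph_model` — typed property graph, TSV round-trip, GraphML export
- `repograph.gd_ranking` — contingencies, LLS, gold-standard selection, WS, D tuning
- `repograph.mesh_sim` — MeSH forest, node distances, Sim
- `repograph.area_scoring` — TAU / RTA / eligibility
- `repograph.mining` — subgraph enumeration, activity normalization, dedup
- `repograph.filters` — side-effect / directionality / ADME cascade
- `repograph.validation` — Sim-tolerant matching, recall curves, ROC AUC
- `repograph.synthetic` — deterministic fixture generator with planted truth
- `repograph.pipeline`, `repograph.cli` — stage orchestration and the
  `repograph` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
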