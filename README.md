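# corrpath

Optimization-driven meta-analysis of case/control expression studies:
select highly differentially expressed genes across experiments with
*incommensurate units*, then connect them by the provably most
correlated cyclic path — a proxy for a signaling path.

## Who this is for

Researchers holding two or more gene × sample expression matrices
(e.g. microarray case/control series from different platforms) who want
a biomarker shortlist and a correlation-ordered cycle among those
genes **without** choosing normalizations, fold-change cutoffs or
p-value thresholds. Both stages are optimization problems with exact
solutions; there are no tuning weights to pick.

## Method in brief

**Stage 1 — Pareto screening by DEA.** Each gene k is scored by J
performance measures f_j(x_k) (default, per experiment: |mean case −
mean control| to maximize, pooled within-group SD to minimize). A gene
is kept when it is *Pareto-efficient*: no other gene is at least as
good in every measure and better in one. Efficiency is decided by the
BCC (variable-returns-to-scale) multiplier linear programs — a gene on
the envelope scores 1 in both the input-oriented form
(max μᵀY₀^max + u₀ s.t. νᵀY₀^min = 1, μᵀY_j^max − νᵀY_j^min + u₀ ≤ 0,
μ, ν ≥ ε) and its output-oriented dual form. Because the envelope is
piecewise linear, the screen is applied repeatedly — detect, remove,
repeat — yielding efficient frontiers 1..F (default F = 10). DEA scores
are invariant to per-column units, which is what lets experiments on
wildly different scales be analyzed jointly, unnormalized.

**Stage 2 — most correlated cyclic path by exact TSP.** For the
selected genes, per experiment, each gene's deviation profile is its
case-sample expression minus its control mean; edges carry |Pearson r|
between profiles. The cycle visiting every gene once with maximum total
|r| is found by an integer program (costs c_ij = 1 − |r_ij|; subtours
excluded by single-commodity flow: the source ships n−1 units, one per
other node, only along used arcs) solved by branch and bound to a
**certified** optimum — with 28 genes the search space is
28! ≈ 3.04 × 10²⁹ directed orderings, so certification matters.
Re-solving on growing gene-list prefixes (5, 10, 15, …) reveals which
adjacent pairs persist; intersecting full-size tours across experiments
gives consensus pairs, optionally annotated with shared pathway
memberships from a local table.

See `docs/methods.md` for formulations, numerical choices and the
synthetic benchmark design.

## Worked example

Generate a synthetic 28-gene study (two experiments on scales 1 and
1000, a planted high-correlation ring) and run both stages:

```bash
corrpath simulate --out demo --seed 7 --n-genes 28 --n-cycle 28
corrpath run-all --config demo/config.yaml
```

Stage 1 logs the screen:

```
INFO corrpath.pipeline: stage1: 28 genes selected; per-frontier counts {1: 5, 4: 5, 3: 9, 2: 9}
```

i.e. all 28 genes are reached within four efficient frontiers (5 genes
on frontier 1, 9 on frontier 2, …). Stage 2 writes, per experiment, the
correlation matrix, the stability report and the optimal tour; for this
study `demo/results/stability_exp1.json` contains

```
"sizes": [5, 10, 15, 20, 25, 28]
"tours": { ..., "28": {"total_weight": 25.794, "optimal": true, ...} }
```

— six exact TSP solves on growing prefixes, all certified optimal, the
full 28-gene cycle carrying total absolute correlation 25.794 (out of
an upper bound of 28 if all adjacent pairs correlated perfectly). The
persistence table shows 27 pairs adjacent at *every* size at which both
genes were present (the planted ring), e.g.

```
{"pair": ["G0000", "G0001"], "fraction": 1.0, "count": 6, "eligible": 6}
```

and `demo/results/consensus_pairs.tsv` lists the pairs adjacent in the
full tours of **both** experiments (here: the planted ring edges, e.g.
`G0000–G0001`, `G0003–G0004`, …).

The same machinery is available as a library — estimator-style classes
`DEAFrontierPeeler` (fit/`labels_` = frontier index per gene) and
`MostCorrelatedCycle` (fit/`tour_`), or per-step functions
(`compute_criteria`, `peel_frontiers`, `abs_pearson_graph`,
`solve_exact`, `incremental_tours`, `consensus_pairs`, …).

Real data enter as TSV: a genes × samples matrix (first column gene
ids, header sample ids) plus a `sample_id<TAB>group` label table
(`control`/`healthy`/`normal` vs `case`/`cancer`/`tumor`), one pair per
experiment, listed in the YAML config. Values are used exactly as
given — no rescaling, no log transform.

## Scope notes

GEO accessions are deliberately not downloaded or parsed here; to
reproduce a published microarray analysis, export the series matrix to
the TSV layout above (e.g. with GEOparse) and list both experiments in
the config. Pathway annotation is an offline join against a
user-supplied `gene<TAB>pathway` table — no web calls are made.
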