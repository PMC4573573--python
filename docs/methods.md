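# Methods

`corrpath` implements a two-stage, optimization-driven analysis of
multiple case/control expression experiments: (1) selection of highly
differentially expressed genes by Pareto-efficiency screening with Data
Envelopment Analysis (DEA), and (2) construction of the maximally
correlated cyclic path among the selected genes by an exact traveling
salesman solve, followed by a stability and cross-experiment consensus
analysis. This note records the models, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Stage 1 — multi-criteria gene screening

### Performance measures

Each gene k becomes a candidate of a discretized multiple-criteria
problem, characterized by J performance measures f_j(x_k) with a
declared direction (maximize or minimize). The default configuration
uses, for every experiment independently:

- `abs_mean_diff` = |mean(case) − mean(control)| — maximize;
- `pooled_sd` = sqrt(((n_case−1)·s²_case + (n_ctrl−1)·s²_ctrl) /
  (n_case + n_ctrl − 2)) — minimize.

A gene that shifts strongly *and* consistently scores well on both.
Crucially, each measure is computed within a single experiment, so
columns may live on arbitrarily different scales — no normalization is
applied, ever, and none is needed: DEA's efficiency scores are invariant
to per-column units (up to the ε-bound discussed below). A pooled
two-sample |t| statistic is available as an alternative maximized
measure; only the pooled-variance form is offered, to keep the measure
set small and interpretable. Welch-type variants are deliberately not
implemented.

Genes with zero pooled SD produce an undefined t; they are assigned 0
(a flat gene carries no evidence) with a warning, and the positivity
adjustment below keeps the LP well posed.

### BCC efficiency and frontier peeling

A gene is *Pareto-efficient* when no other gene is at least as good in
every measure and strictly better in one. The screen solves, for every
gene, two variable-returns-to-scale BCC multiplier linear programs over
the maximized columns Y^max and minimized columns Y^min:

- input-oriented: max μᵀY₀^max + u₀ s.t. νᵀY₀^min = 1,
  μᵀY_j^max − νᵀY_j^min + u₀ ≤ 0 ∀j, μ, ν ≥ ε;
- output-oriented: min νᵀY₀^min + v₀ s.t. μᵀY₀^max = 1,
  νᵀY_j^min − μᵀY_j^max + v₀ ≥ 0 ∀j, μ, ν ≥ ε.

A gene is efficient iff both scores equal 1 within `score_tol`. The
free scalars u₀, v₀ are implemented as single unrestricted variables
rather than differences of two nonnegative ones — the same polytope
with fewer degenerate rays. The non-Archimedean bound ε (default 1e-6)
keeps all multipliers strictly positive so weakly dominated genes
cannot hide behind zero weights; shrinking ε can only grow the
efficient set (verified by test at ε ∈ {1e-4, 1e-6, 1e-8}).

Because the DEA envelope is piecewise linear, genes in non-convex
stretches of the Pareto frontier escape a single pass. The screen is
therefore applied successively: detect the efficient set, remove it,
repeat, up to `num_frontiers` rounds (default 10, configurable — the
count is a screening depth, not a statistically derived quantity).
Every gene gets a frontier index 1..F or none.

Numerical choices:

- **Positivity.** The BCC forms require strictly positive data
  (νᵀY₀^min = 1 is unattainable at 0). Any column dipping below
  `positivity_delta` (1e-6) is shifted up to that floor, with a warning.
  The shift is recorded in run metadata.
- **One-sided measure sets.** BCC needs both a maximized and a
  minimized side. If the configured measures are all of one direction, a
  constant dummy column of 1s is added on the other side — the standard
  single-constant-input DEA device; it leaves the ranking untouched.
- **Degenerate output orientation.** With a dummy *maximized* side the
  output-oriented LP discriminates only at O(ε); classification then
  rests on the input orientation. Mixed-direction configurations (the
  default) do not have this issue.
- **Ties.** Identical criteria rows are symmetric in the LP and become
  efficient together; no tie-breaking is applied.
- **Efficiency tolerance.** `score_tol` = 1e-6 on |score − 1|, matching
  ε's magnitude and double-precision LP practice. Solver: HiGHS via
  `scipy.optimize.linprog`; correctness is asserted against
  solver-independent oracles (below), not against a solver's word.

Two oracles back the screen in the test suite: an exact O(K²) pairwise
dominance enumeration (soundness: no efficient gene is ever dominated)
and, for the two-measure case, a direct geometric construction of the
Pareto-nondominated convex-envelope vertices (completeness).

### Cross-experiment sign filter

With ≥ 2 experiments, selected genes can be required to shift in the
same direction everywhere (strictly nonzero signed mean difference of
identical sign in every experiment; a zero difference agrees with
nothing). With one experiment the filter passes everything, with a
warning.

## Stage 2 — the most correlated cyclic path

### Deviation profiles and the correlation graph

For each selected gene, the default profile is its expression in every
case sample minus its own control-group mean (length = number of case
samples; requires ≥ 3). This reads "difference from the healthy
baseline" per tumor while handling unequal group sizes; a
`group_centered` alternative (every sample minus its own group mean,
concatenated) is available when case samples are scarce, and the choice
is recorded in run metadata. Note the subtracted control mean is a
per-gene constant, so its sampling error does not perturb correlations.

Edges carry |Pearson r| between profiles — the absolute value because
anticorrelation (inhibition) is as strong a link as excitation.
Spearman is available behind a flag. Pairs with a zero-variance profile
have undefined r; they get weight 0 and are listed as degenerate rather
than aborting the run.

### Exact TSP over the complete graph

The most correlated cyclic path is the Hamiltonian cycle maximizing the
sum of edge weights. Since every tour has exactly n edges, maximizing
Σ|r| equals minimizing Σ(1 − |r|); costs c_ij = 1 − |r_ij| ∈ [0, 1].
Subtours are excluded by a single-commodity-flow formulation: binary
arc variables y_ij with in/out-degree 1 per node; flow variables
x_ij ≥ 0 with node-arc incidence balance Nx = b, where the source node
(lexicographically smallest id; the optimum is source-independent)
supplies n−1 units and every other node demands 1; and forcing
constraints x_ij ≤ (n−1)·y_ij. Any feasible arc set is then one
connected cycle.

The integer program is solved by branch and bound (HiGHS via
`scipy.optimize.milp`) at zero relative MIP gap — the returned tour is
certified optimal. If the time limit (default 3600 s) expires first, an
error carrying the incumbent and its bound gap is raised; an
uncertified tour is never silently presented as the answer. The
returned cycle is additionally re-validated outside the solver
(degree 2, single cycle) and reported in canonical form: rotated to the
lexicographically smallest node, oriented toward its smaller neighbor.
For n ≤ 10, an exhaustive (n−1)!-permutation oracle provides an
independent check; the two agree on every random instance in the test
suite (n = 4..9). At n = 28 the tour space is 28! ≈ 3.04 × 10²⁹
directed orderings, far beyond enumeration — hence the ILP.

### Stability and consensus

Solving one TSP says nothing about robustness, so the stability study
re-solves on growing prefixes of the frontier-ordered gene list
(default step 5: sizes 5, 10, …, full length; a trailing remainder is
included as the final size). For every gene pair we report the number
of sizes at which it was adjacent in the optimal tour and the number of
sizes at which both endpoints were even present; their ratio is the
persistence fraction (a late-arriving gene is not penalized for sizes
it could not attend). `persistent_pairs` filters at a configurable
minimum fraction (default 1.0) but always reports the fraction, since
partially persistent segments are informative too. Within a frontier,
genes are ordered by descending first-round input-orientation score,
then id — deterministic and recorded in metadata.

Across experiments, `consensus_pairs` intersects full-size tour
adjacencies over all experiments sharing the gene universe. Pathway
context is strictly offline: a user-supplied two-column TSV
(gene → pathway id) is joined against adjacent pairs; genes absent from
the table contribute the empty set. No network access anywhere.

## The synthetic benchmark

`simulate.generate_study` draws studies with known ground truth:
several experiments over the same genes (default two, shaped like a
small cancer microarray study: 8 control vs 25 case samples), Gaussian
background noise (sd 1.0) around a log-scale-like baseline of 8.0,
planted differentially expressed genes shifted by a chosen effect (in
within-group-SD units, consistent sign across experiments), a planted
gene ring with target adjacent |correlation| (default 0.95 over 10
genes), and per-experiment scale factors/offsets (default 1 and 1000)
that place experiments on incommensurate scales without touching their
internal structure. Everything is deterministic given the seed.

The planted ring deserves detail. Positive-semidefiniteness forces any
ring with adjacent correlation r to carry distance-2 chords of at least
2r² − 1 (≈ 0.805 at r = 0.95); how far the chords sit *above* that
floor determines how decisively the optimal tour identifies the planted
ring under sampling noise. Short cycles (cos(2π/L) < target) therefore
use a latent-plane construction: gene i's case deviation is
√a²·F + √b²·(cos φ_i·A + sin φ_i·B), with φ_i = 2πi/L equally spaced
on a circle over two latent factors, a common factor F, and
a² = (target − cos 2π/L)/(1 − cos 2π/L). Every adjacent pair then has
correlation exactly `target` in expectation and the strongest chord
stays near the PSD floor (≈ 0.82 at L = 10), a dominance margin of
≈ 0.26 per two-edge exchange — wide enough that the exact tour
recovered the planted ring in 100/100 draws at 25 case samples. Long
cycles, where the circle is infeasible, fall back to a wrapped AR(1)
circulant (corr(d) ∝ ρ^d + ρ^(L−d)) whose chords decay geometrically;
its margin shrinks with L, so planted-ring recovery for long
high-correlation cycles is *not* guaranteed — an inherent property of
such rings, not of the solver (the tours remain certified optimal).

`recovery_experiment` runs the full pipeline on one planted study and
reports: the fraction of planted genes reaching the first F frontiers
(DE recall), whether the optimal tour restricted to the planted subset
equals the planted ring in every experiment, and the recall of planted
edges among pairs adjacent in that restricted tour in all experiments.

What passing these tests shows — and does not. The generator exercises
incommensurate scales, conflicting criteria, planted rings and
direction consistency, but its noise is Gaussian and homoscedastic,
genes outside the ring are independent, and there are no batch effects,
probe-level artifacts (RMA/MAS5-style), missingness patterns, or
heavy-tailed outliers. Success on the benchmark demonstrates the
optimization machinery is correct and units-invariant; it does not by
itself validate biological conclusions on real arrays.

## Problem sizes used in the automated checks

The shipped checks run 100 random screening instances (≤ 40 genes × ≤ 4
measures) against both oracles, 50 TSP instances per size n = 4..9
against enumeration (20 per size in the acceptance script), 25 planted
studies for pipeline recovery, and one 28-gene stability run (sizes
5–28). These sizes keep the whole suite in the low minutes on one CPU
while leaving every check statistically meaningful; all are constants
at the top of the relevant tests and trivially enlarged.

## Known limitations

- BCC units-invariance is exact only at ε = 0; with ε = 1e-6 an extreme
  rescaling could in principle flip a borderline efficiency call. None
  was observed at factor-1000 rescalings in the tests.
- The flow ILP's linear relaxation is weak for large n; practical solve
  times are seconds up to n ≈ 30 but grow steeply beyond. Typical
  post-screening shortlists (≈ 30–100 genes) are within reach;
  thousands of genes are not, by design — Stage 1 exists to shrink the
  list first.
- Probe identifiers are taken as given; no annotation mapping or
  probe-to-gene collapsing beyond the duplicate-row policy
  (`max_abs_mean` by default, `first`/`mean` selectable).
- Whether input matrices are log-scaled is the user's responsibility;
  values are consumed as-is and this is recorded in run metadata.
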