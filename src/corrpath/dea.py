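"""Pareto-efficient gene detection via BCC Data Envelopment Analysis.

Each gene is a candidate of a discretized multiple-criteria problem.  A
gene is declared efficient when both variable-returns-to-scale BCC
multiplier linear programs — input oriented and output oriented — score it
at exactly 1 against the envelope of all candidates:

input oriented (for candidate 0, measures split into maximized columns
``Y^max`` and minimized columns ``Y^min``)::

    max  mu' Y0_max + u0
    s.t. nu' Y0_min = 1
         mu' Yj_max - nu' Yj_min + u0 <= 0   for every candidate j
         mu >= eps, nu >= eps, u0 free

output oriented::

    min  nu' Y0_min + v0
    s.t. mu' Y0_max = 1
         nu' Yj_min - mu' Yj_max + v0 >= 0   for every candidate j
         mu >= eps, nu >= eps, v0 free

The non-Archimedean bound ``eps`` (default 1e-6) keeps every multiplier
strictly positive so weakly dominated candidates cannot hide behind a
zero weight.  Because the envelope is piecewise linear, candidates in
non-convex parts of the Pareto frontier escape a single pass; successive
"peeling" re-runs the analysis after removing each detected frontier,
yielding frontier indices 1..F (default F=10).

An exact pairwise-dominance enumeration (:func:`pareto_bruteforce`) and a
direct 2-D convex-envelope construction (:func:`convex_frontier_2d`) are
provided as independent oracles; they share no code with the LP path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .criteria import CriteriaMatrix
from .exceptions import DataValidationError, SolverError

logger = logging.getLogger(__name__)


@dataclass
class DEAConfig:
    """Numeric knobs of the DEA stage.

    epsilon : non-Archimedean lower bound on multipliers (default 1e-6).
    num_frontiers : how many frontiers to peel (default 10).
    score_tol : |score - 1| tolerance for calling a gene efficient.
    positivity_delta : minimum value any measure column may take; columns
        falling below are shifted up (BCC needs strictly positive data).
    """

    epsilon: float = 1e-6
    num_frontiers: int = 10
    score_tol: float = 1e-6
    positivity_delta: float = 1e-6

    def __post_init__(self):
        for name in ("epsilon", "score_tol", "positivity_delta"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"DEAConfig.{name} must be > 0")
        if self.num_frontiers < 1:
            raise DataValidationError("DEAConfig.num_frontiers must be >= 1")


@dataclass
class EfficiencyScores:
    gene_ids: list
    input_score: np.ndarray
    output_score: np.ndarray
    efficient: np.ndarray

    def efficient_genes(self):
        return [g for g, e in zip(self.gene_ids, self.efficient) if e]


@dataclass
class FrontierAssignment:
    """Frontier index per gene: 1..F, or None if never selected."""

    gene_ids: list
    frontier: list
    first_round_input_score: dict = field(default_factory=dict)

    def genes_in_frontier(self, f):
        return [g for g, fr in zip(self.gene_ids, self.frontier) if fr == f]

    def selected_genes(self):
        """Genes in any frontier, ordered by (frontier, -round1 score, id)."""
        sel = [(f, g) for g, f in zip(self.gene_ids, self.frontier)
               if f is not None]
        return [g for f, g in sorted(
            sel, key=lambda t: (t[0],
                                -self.first_round_input_score.get(t[1], 0.0),
                                t[1]))]


# ---------------------------------------------------------------------------
# dominance / brute-force oracle

def _as_minimization(values, directions):
    """Flip maximized columns so dominance is uniformly 'smaller is better'."""
    v = np.asarray(values, dtype=float).copy()
    for j, d in enumerate(directions):
        if d == "maximize":
            v[:, j] = -v[:, j]
        elif d != "minimize":
            raise DataValidationError(f"unknown direction '{d}'")
    return v


def dominates(u, v, directions):
    """Pareto dominance: u at least as good everywhere, better somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or len(u) != len(directions):
        raise DataValidationError("dominates: length mismatch")
    m = _as_minimization(np.vstack([u, v]), directions)
    return bool(np.all(m[0] <= m[1]) and np.any(m[0] < m[1]))


def pareto_bruteforce(criteria):
    """Exact nondominated gene set by full pairwise enumeration.

    Quadratic in the number of genes; used as the independent oracle for
    the LP-based detector.
    """
    m = _as_minimization(criteria.values, criteria.directions)
    n = m.shape[0]
    nondominated = set()
    for k in range(n):
        dominated = False
        for other in range(n):
            if other == k:
                continue
            if np.all(m[other] <= m[k]) and np.any(m[other] < m[k]):
                dominated = True
                break
        if not dominated:
            nondominated.add(criteria.gene_ids[k])
    return nondominated


def convex_frontier_2d(x, y):
    """Indices of Pareto-nondominated convex-envelope vertices, one
    maximized measure ``x`` and one minimized measure ``y``.

    Direct geometric construction (sort + lower convex hull of the
    nondominated staircase); independent of any LP.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    # nondominated staircase: no other point with x >= and y <= (one strict)
    nd = []
    for k in range(n):
        dominated = any(
            (x[o] >= x[k]) and (y[o] <= y[k])
            and ((x[o] > x[k]) or (y[o] < y[k]))
            for o in range(n) if o != k)
        if not dominated:
            nd.append(k)
    nd.sort(key=lambda k: (x[k], y[k]))
    # lower convex hull over (x, y): keep right turns only
    hull = []
    for k in nd:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = ((x[hull[-2]], y[hull[-2]]),
                                  (x[hull[-1]], y[hull[-1]]))
            cross = (x2 - x1) * (y[k] - y1) - (y2 - y1) * (x[k] - x1)
            if cross <= 0:  # hull[-1] lies on/above the chord: not a vertex
                hull.pop()
            else:
                break
        hull.append(k)
    return sorted(hull)


# ---------------------------------------------------------------------------
# BCC linear programs

def _positivity_adjust(values, directions, delta):
    """Shift columns so every entry is >= delta; add a constant dummy
    column when all measures share one direction (BCC needs both sides)."""
    v = np.asarray(values, dtype=float).copy()
    dirs = list(directions)
    shifts = np.zeros(v.shape[1])
    for j in range(v.shape[1]):
        cmin = v[:, j].min()
        if cmin < delta:
            shifts[j] = delta - cmin
            v[:, j] += shifts[j]
    if np.any(shifts > 0):
        logger.warning("positivity adjustment applied to %d columns",
                       int(np.sum(shifts > 0)))
    if "maximize" not in dirs:
        v = np.column_stack([v, np.ones(v.shape[0])])
        dirs = dirs + ["maximize"]
    elif "minimize" not in dirs:
        v = np.column_stack([v, np.ones(v.shape[0])])
        dirs = dirs + ["minimize"]
    max_idx = [j for j, d in enumerate(dirs) if d == "maximize"]
    min_idx = [j for j, d in enumerate(dirs) if d == "minimize"]
    return v[:, max_idx], v[:, min_idx], shifts


def _solve_bcc(Ymax, Ymin, k0, epsilon, orientation):
    """Solve one BCC multiplier LP; returns (score, multipliers dict)."""
    n, p = Ymax.shape
    q = Ymin.shape[1]
    # variable vector: [mu (p), nu (q), u0 (free)]
    nvar = p + q + 1
    bounds = [(epsilon, None)] * (p + q) + [(None, None)]
    # envelope constraints: mu'Yj_max - nu'Yj_min + u0 <= 0 for all j
    A_ub = np.hstack([Ymax, -Ymin, np.ones((n, 1))])
    b_ub = np.zeros(n)
    if orientation == "input":
        c = np.zeros(nvar)
        c[:p] = -Ymax[k0]          # maximize mu'Y0_max + u0
        c[-1] = -1.0
        A_eq = np.zeros((1, nvar))
        A_eq[0, p:p + q] = Ymin[k0]  # nu'Y0_min = 1
        sign = -1.0
    elif orientation == "output":
        # shared envelope rows carry +u0 <= 0 form, so here u0 == -v0
        c = np.zeros(nvar)
        c[p:p + q] = Ymin[k0]      # minimize nu'Y0_min + v0
        c[-1] = -1.0
        A_eq = np.zeros((1, nvar))
        A_eq[0, :p] = Ymax[k0]       # mu'Y0_max = 1
        sign = 1.0
    else:
        raise DataValidationError(f"unknown orientation '{orientation}'")
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise SolverError(
            f"BCC {orientation}-oriented LP infeasible for candidate {k0}; "
            f"epsilon={epsilon} may be too large for the data scale — "
            f"try reducing it")
    if res.status != 0:
        raise SolverError(
            f"BCC {orientation}-oriented LP failed for candidate {k0} "
            f"(status {res.status}: {res.message}); an unbounded model "
            f"indicates a bug")
    score = sign * res.fun
    mult = {"mu": res.x[:p].copy(), "nu": res.x[p:p + q].copy(),
            "u0": float(res.x[-1])}
    return float(score), mult


def bcc_score(criteria, k0, config=None, orientation="input"):
    """Efficiency score of gene ``k0`` against the whole candidate set.

    Input-oriented scores are <= 1, output-oriented >= 1; a gene on the
    envelope scores 1 in both (within solver tolerance).
    """
    config = config or DEAConfig()
    Ymax, Ymin, _ = _positivity_adjust(
        criteria.values, criteria.directions, config.positivity_delta)
    return _solve_bcc(Ymax, Ymin, k0, config.epsilon, orientation)


def dea_efficient_set(criteria, config=None):
    """Score every gene in both orientations and flag the efficient ones."""
    config = config or DEAConfig()
    Ymax, Ymin, _ = _positivity_adjust(
        criteria.values, criteria.directions, config.positivity_delta)
    n = Ymax.shape[0]
    in_s = np.empty(n)
    out_s = np.empty(n)
    for k in range(n):
        in_s[k], _ = _solve_bcc(Ymax, Ymin, k, config.epsilon, "input")
        out_s[k], _ = _solve_bcc(Ymax, Ymin, k, config.epsilon, "output")
    eff = (np.abs(in_s - 1.0) <= config.score_tol) \
        & (np.abs(out_s - 1.0) <= config.score_tol)
    return EfficiencyScores(list(criteria.gene_ids), in_s, out_s, eff)


def peel_frontiers(criteria, config=None):
    """Successive envelope extraction: frontier f = efficient set of the
    genes remaining after removing frontiers 1..f-1.

    Stops early once every gene is assigned; genes still unassigned after
    ``num_frontiers`` rounds get frontier ``None``.
    """
    config = config or DEAConfig()
    remaining = list(criteria.gene_ids)
    frontier = {g: None for g in remaining}
    round1 = {}
    for f in range(1, config.num_frontiers + 1):
        if not remaining:
            break
        sub = criteria.subset(remaining)
        scores = dea_efficient_set(sub, config)
        if f == 1:
            round1 = dict(zip(scores.gene_ids, scores.input_score))
        eff = scores.efficient_genes()
        if not eff:
            logger.warning("peel_frontiers: empty frontier %d with %d genes "
                           "remaining; stopping", f, len(remaining))
            break
        for g in eff:
            frontier[g] = f
        remaining = [g for g in remaining if frontier[g] is None]
    return FrontierAssignment(
        list(criteria.gene_ids),
        [frontier[g] for g in criteria.gene_ids],
        round1,
    )


# ---------------------------------------------------------------------------
# estimator facade

class DEAFrontierPeeler(BaseEstimator):
    """Frontier-peeling gene selector with a clusterer-style interface.

    ``fit(X)`` takes the criteria matrix (candidates x measures) and
    assigns each candidate a frontier label in ``labels_`` (1-based; -1
    marks candidates outside the first ``num_frontiers`` frontiers).

    Parameters
    ----------
    directions : list of {"maximize", "minimize"}
        Optimization direction per column of X.
    epsilon, num_frontiers, score_tol, positivity_delta : see :class:`DEAConfig`.
    """

    def __init__(self, directions=None, epsilon=1e-6, num_frontiers=10,
                 score_tol=1e-6, positivity_delta=1e-6):
        self.directions = directions
        self.epsilon = epsilon
        self.num_frontiers = num_frontiers
        self.score_tol = score_tol
        self.positivity_delta = positivity_delta

    def _config(self):
        return DEAConfig(self.epsilon, self.num_frontiers,
                         self.score_tol, self.positivity_delta)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataValidationError("X must be 2-D (candidates x measures)")
        dirs = (list(self.directions) if self.directions is not None
                else ["maximize"] * X.shape[1])
        if len(dirs) != X.shape[1]:
            raise DataValidationError(
                "directions length must match number of columns")
        from .criteria import PerformanceMeasureSpec  # local to avoid cycle
        specs = [PerformanceMeasureSpec(f"pm{j}", d, "signed_mean_diff", "_")
                 for j, d in enumerate(dirs)]
        crit = CriteriaMatrix([str(i) for i in range(X.shape[0])], specs, X)
        assignment = peel_frontiers(crit, self._config())
        self.frontier_assignment_ = assignment
        self.labels_ = np.array(
            [f if f is not None else -1 for f in assignment.frontier])
        scores = dea_efficient_set(crit, self._config())
        self.input_scores_ = scores.input_score
        self.output_scores_ = scores.output_score
        self.support_ = self.labels_ > 0
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
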