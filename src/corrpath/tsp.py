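"""Exact maximum-|correlation| Hamiltonian cycles.

The most correlated cyclic path over n genes is a traveling-salesman
tour: maximizing the sum of absolute pairwise correlations over a cycle
visiting every gene once is equivalent to minimizing costs
``c_ij = 1 - |r_ij|`` (every tour has exactly n edges, so the affine map
preserves the argmax and keeps costs in [0, 1]).

Subtours are excluded with a single-commodity-flow formulation: the
source node holds n-1 flow units and must deliver one unit to every
other node, flow may only travel on used arcs (``x_ij <= (n-1) y_ij``),
and flow balance is written through the node-arc incidence matrix.  Any
arc set satisfying the degree and flow constraints is therefore one
connected cycle.  The integer program is solved to proven optimality
(branch and bound, zero relative gap); a heuristic incumbent is never
reported as a result.

For n <= 10 an exhaustive permutation oracle is provided as an
independent check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix
from sklearn.base import BaseEstimator

from .exceptions import DataValidationError, SolverError, SolverLimitError

ENUMERATION_GUARD = 10  # (n-1)! tours; 9! = 362880 is the ceiling we walk


@dataclass
class TSPModel:
    """Flow-based integer program for one correlation graph.

    ``cost`` is the symmetric n x n matrix of ``1 - |r|``; ``source`` is
    the index of the flow source node (lexicographically smallest id),
    which holds ``n - 1`` supply units while every other node demands 1.
    """

    node_ids: list
    cost: np.ndarray
    source: int

    @property
    def n(self):
        return len(self.node_ids)

    @property
    def arcs(self):
        """All ordered pairs (i, j), i != j."""
        n = self.n
        return [(i, j) for i in range(n) for j in range(n) if i != j]

    @property
    def supply(self):
        b = -np.ones(self.n)
        b[self.source] = self.n - 1
        return b


@dataclass
class Tour:
    """A Hamiltonian cycle in canonical form.

    Canonical: rotated so the lexicographically smallest node id comes
    first, oriented so the second node is the smaller of its two
    neighbors.  ``total_weight`` sums |correlation| over the n cycle
    edges; ``optimal`` is True only under a solver optimality certificate
    or exhaustive enumeration.
    """

    node_ids: list
    total_weight: float
    optimal: bool
    canonical: bool = True
    stats: dict = field(default_factory=dict)

    def edges(self):
        n = len(self.node_ids)
        return [(self.node_ids[i], self.node_ids[(i + 1) % n])
                for i in range(n)]

    def adjacency(self):
        """Unordered adjacent pairs of the cycle."""
        return {frozenset(e) for e in self.edges()}


def canonical_cycle(nodes):
    """Canonical representative of a cyclic node sequence."""
    nodes = list(nodes)
    n = len(nodes)
    k = nodes.index(min(nodes))
    rot = nodes[k:] + nodes[:k]
    if n > 2 and rot[-1] < rot[1]:
        rot = [rot[0]] + rot[1:][::-1]
    return rot


def build_model(graph):
    """Translate a correlation graph into the flow-TSP integer program."""
    n = len(graph.gene_ids)
    if n < 3:
        raise DataValidationError(f"TSP needs >= 3 nodes, got {n}")
    cost = 1.0 - np.asarray(graph.weights, dtype=float)
    np.fill_diagonal(cost, 0.0)
    source = graph.gene_ids.index(min(graph.gene_ids))
    return TSPModel(list(graph.gene_ids), cost, source)


def tour_weight(graph, order):
    """Total |correlation| of a cyclic visiting order (closing edge included)."""
    order = list(order)
    if sorted(order) != sorted(graph.gene_ids):
        raise DataValidationError(
            "tour order must be a permutation of the graph nodes")
    pos = {g: i for i, g in enumerate(graph.gene_ids)}
    idx = [pos[g] for g in order]
    w = np.asarray(graph.weights, dtype=float)
    return float(sum(w[idx[i], idx[(i + 1) % len(idx)]]
                     for i in range(len(idx))))


def _extract_cycle(model, y):
    """Successor walk + independent validity check (degree 2, one cycle)."""
    n = model.n
    succ = {}
    for i in range(n):
        outs = [j for j in range(n) if j != i and y[i, j] > 0.5]
        if len(outs) != 1:
            raise SolverError(f"solver arc set violates out-degree at node {i}")
        succ[i] = outs[0]
    ins = np.zeros(n, dtype=int)
    for i in range(n):
        ins[succ[i]] += 1
    if not np.all(ins == 1):
        raise SolverError("solver arc set violates in-degree 1")
    order = [0]
    while True:
        nxt = succ[order[-1]]
        if nxt == 0:
            break
        if nxt in order:
            raise SolverError("solver arc set contains a subtour")
        order.append(nxt)
    if len(order) != n:
        raise SolverError("solver arc set contains a subtour")
    return order


def solve_exact(model, time_limit=3600.0):
    """Solve the flow ILP to certified optimality.

    Raises :class:`SolverLimitError` (carrying the incumbent, if any)
    when the time limit expires without an optimality certificate — an
    uncertified incumbent is never silently returned.
    """
    n = model.n
    arcs = model.arcs
    m = len(arcs)
    aidx = {a: k for k, a in enumerate(arcs)}
    # variables: y (m binary) then x (m continuous >= 0)
    c = np.concatenate([np.array([model.cost[i, j] for (i, j) in arcs]),
                        np.zeros(m)])
    rows, cols, vals = [], [], []
    rhs_lo, rhs_hi = [], []
    row = 0
    # out-degree and in-degree = 1
    for i in range(n):
        for j in range(n):
            if i != j:
                rows.append(row), cols.append(aidx[(i, j)]), vals.append(1.0)
        rhs_lo.append(1.0), rhs_hi.append(1.0)
        row += 1
    for j in range(n):
        for i in range(n):
            if i != j:
                rows.append(row), cols.append(aidx[(i, j)]), vals.append(1.0)
        rhs_lo.append(1.0), rhs_hi.append(1.0)
        row += 1
    # flow conservation N x = b (node-arc incidence: +1 out, -1 in)
    b = model.supply
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append(row + i), cols.append(m + aidx[(i, j)]), vals.append(1.0)
            rows.append(row + j), cols.append(m + aidx[(i, j)]), vals.append(-1.0)
    for i in range(n):
        rhs_lo.append(b[i]), rhs_hi.append(b[i])
    row += n
    # forcing x_ij - (n-1) y_ij <= 0
    for k in range(m):
        rows.append(row), cols.append(m + k), vals.append(1.0)
        rows.append(row), cols.append(k), vals.append(-(n - 1.0))
        rhs_lo.append(-np.inf), rhs_hi.append(0.0)
        row += 1
    A = csr_matrix((vals, (rows, cols)), shape=(row, 2 * m))
    constraints = LinearConstraint(A, rhs_lo, rhs_hi)
    integrality = np.concatenate([np.ones(m), np.zeros(m)])
    lb = np.zeros(2 * m)
    ub = np.concatenate([np.ones(m), np.full(m, n - 1.0)])
    res = milp(c, constraints=constraints, integrality=integrality,
               bounds=(lb, ub),
               options={"time_limit": float(time_limit), "mip_rel_gap": 0.0})
    if res.status == 1 or (res.status != 0 and res.x is not None):
        incumbent = None
        if res.x is not None:
            y = np.zeros((n, n))
            for k, (i, j) in enumerate(arcs):
                y[i, j] = res.x[k]
            try:
                order = _extract_cycle(model, y)
                ids = canonical_cycle([model.node_ids[i] for i in order])
                incumbent = Tour(ids, float(n - res.fun), optimal=False,
                                 stats={"gap": res.mip_gap})
            except SolverError:
                incumbent = None
        raise SolverLimitError(
            f"TSP time limit {time_limit}s reached without optimality "
            f"certificate", incumbent=incumbent,
            gap=getattr(res, "mip_gap", None))
    if res.status != 0:
        raise SolverError(f"TSP solve failed: {res.message}")
    y = np.zeros((n, n))
    for k, (i, j) in enumerate(arcs):
        y[i, j] = res.x[k]
    order = _extract_cycle(model, y)
    ids = canonical_cycle([model.node_ids[i] for i in order])
    weights = 1.0 - model.cost
    total = float(sum(
        weights[model.node_ids.index(a)][model.node_ids.index(b_)]
        for a, b_ in zip(ids, ids[1:] + ids[:1])))
    return Tour(ids, total, optimal=True,
                stats={"mip_gap": float(getattr(res, "mip_gap", 0.0)),
                       "mip_node_count": int(getattr(res, "mip_node_count", 0)
                                             or 0)})


def tour_space_size(n):
    """Exact number of directed cyclic orderings of n nodes (n!)."""
    return math.factorial(n)


def sci_notation(value, sig=3, mode="truncate"):
    """Scientific-notation string of a (possibly huge) integer.

    ``mode="truncate"`` cuts the mantissa after ``sig`` significant
    digits without rounding; ``"round"`` rounds to nearest.
    """
    s = str(int(value))
    exp = len(s) - 1
    digits = s[:sig + 2]
    mant = int(digits) / 10 ** (len(digits) - 1)
    if mode == "truncate":
        factor = 10 ** (sig - 1)
        mant = math.floor(mant * factor) / factor
    else:
        mant = round(mant, sig - 1)
    return f"{mant:.{sig - 1}f}e+{exp}"


def enumerate_oracle(graph):
    """Brute-force maximum-weight tour by walking all (n-1)! permutations.

    Hard-guarded at n <= 10; ties are broken toward the lexicographically
    smallest canonical sequence.
    """
    n = len(graph.gene_ids)
    if n < 3:
        raise DataValidationError("enumerate_oracle needs >= 3 nodes")
    if n > ENUMERATION_GUARD:
        raise DataValidationError(
            f"enumerate_oracle refuses n={n} (> {ENUMERATION_GUARD}): "
            f"{n}! tours is combinatorially infeasible")
    w = np.asarray(graph.weights, dtype=float)
    first = 0
    best_weight = -np.inf
    best = None
    rest = list(range(1, n))
    for perm in itertools.permutations(rest):
        idx = (first,) + perm
        total = w[idx[-1], first]
        for a, b in zip(idx, idx[1:]):
            total += w[a, b]
        if total > best_weight + 1e-15:
            best_weight = total
            best = canonical_cycle([graph.gene_ids[i] for i in idx])
        elif abs(total - best_weight) <= 1e-15:
            cand = canonical_cycle([graph.gene_ids[i] for i in idx])
            if cand < best:
                best = cand
    return Tour(best, float(best_weight), optimal=True,
                stats={"tours_examined": math.factorial(n - 1)})


class MostCorrelatedCycle(BaseEstimator):
    """Estimator facade: fit a maximum-|correlation| cycle on profiles.

    ``fit(X)`` accepts either per-gene deviation profiles (rows = genes,
    columns = samples; pairwise |Pearson r| is computed) or, with
    ``precomputed=True``, a symmetric |correlation| weight matrix.

    Attributes (after fit): ``graph_``, ``tour_``, ``tour_weight_``.
    """

    def __init__(self, precomputed=False, time_limit=3600.0, node_ids=None):
        self.precomputed = precomputed
        self.time_limit = time_limit
        self.node_ids = node_ids

    def fit(self, X, y=None):
        from .correlation import CorrelationGraph, abs_pearson_graph, \
            DeviationProfiles
        X = np.asarray(X, dtype=float)
        ids = (list(self.node_ids) if self.node_ids is not None
               else [f"n{i}" for i in range(X.shape[0])])
        if self.precomputed:
            self.graph_ = CorrelationGraph(ids, X)
        else:
            profiles = DeviationProfiles("fit", ids, X,
                                         "case_minus_control_mean")
            self.graph_ = abs_pearson_graph(profiles)
        model = build_model(self.graph_)
        self.tour_ = solve_exact(model, time_limit=self.time_limit)
        self.tour_weight_ = self.tour_.total_weight
        return self

    def predict(self, X=None):
        """Canonical node order of the fitted cycle."""
        return list(self.tour_.node_ids)
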