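"""Synthetic multi-experiment studies with known ground truth.

The generator emulates the data regime the pipeline targets: several
case/control expression studies of the same genes measured on
deliberately different (incommensurate) scales, a planted set of
differentially expressed genes whose direction of change agrees across
experiments, and a planted gene cycle whose case deviations are strongly
correlated around the ring.  Defaults mirror a small cancer microarray
study: 8 control vs 25 case samples per experiment, unit within-group
noise on a log-like scale, a 3-SD expression shift for planted genes and
a 0.95 target |r| along the planted cycle.

The planted ring must satisfy two competing constraints: every adjacent
pair should carry the target |r|, while non-adjacent (chord) pairs stay
as weak as positive-semidefiniteness permits (any ring with adjacent
correlation r forces distance-2 chords >= 2r^2 - 1, about 0.805 at
r = 0.95) — the wider that gap, the more decisively the optimal tour
pins down the planted ring against sampling noise.  Short cycles use a
latent-plane construction: genes sit at equally spaced angles on a
circle spanned by two latent factors, plus a shared common factor that
lifts the adjacent correlation to the target exactly; chords then land
near the PSD floor.  When the circle alone is already tighter than the
target (long cycles, cos(2*pi/L) >= target) the ring falls back to a
wrapped first-order autoregressive process on the cycle, whose chords
decay geometrically; its dominance margin shrinks with cycle length,
an inherent property of long high-correlation rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataValidationError
from .io import ExpressionExperiment, StudyCollection, intersect_genes
from . import criteria as criteria_mod
from . import correlation as correlation_mod
from . import dea as dea_mod
from . import tsp as tsp_mod


@dataclass
class ExperimentSpec:
    """Shape and scale of one synthetic experiment."""

    n_control: int = 8
    n_case: int = 25
    scale_factor: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise DataValidationError("scale_factor must be > 0")
        if self.n_control < 2 or self.n_case < 2:
            raise DataValidationError("need >= 2 samples per group")


@dataclass
class SyntheticSpec:
    """Ground-truth description of a planted study.

    ``de_genes`` maps gene index -> (effect size in within-group SD
    units, sign in {+1, -1}); ``cycle_genes`` is the ordered ring.  By
    default the cycle genes are exactly the DE genes.
    """

    n_genes: int = 50
    experiments: list = field(default_factory=lambda: [
        ExperimentSpec(scale_factor=1.0),
        ExperimentSpec(scale_factor=1000.0),
    ])
    de_genes: dict = field(default_factory=dict)
    cycle_genes: list = field(default_factory=list)
    cycle_strength: float = 0.95
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.cycle_genes and len(self.cycle_genes) < 4:
            raise DataValidationError("planted cycle needs >= 4 genes")
        bad = [g for g in list(self.de_genes) + list(self.cycle_genes)
               if not 0 <= g < self.n_genes]
        if bad:
            raise DataValidationError(
                f"planted gene indices out of range: {bad[:5]}")
        if len(set(self.cycle_genes)) != len(self.cycle_genes):
            raise DataValidationError("cycle gene indices must be unique")
        if not 0 < self.cycle_strength < 1:
            raise DataValidationError("cycle_strength must be in (0, 1)")
        if self.noise_sd <= 0:
            raise DataValidationError("noise_sd must be > 0")

    @classmethod
    def default_planted(cls, seed=0, n_genes=50, n_cycle=10, effect=3.0,
                        cycle_strength=0.95, **kw):
        """The standard strongly planted study: an n_cycle-gene ring of
        DE genes (alternating sign) among n_genes total."""
        cycle = list(range(n_cycle))
        de = {g: (effect, 1 if i % 2 == 0 else -1)
              for i, g in enumerate(cycle)}
        return cls(n_genes=n_genes, de_genes=de, cycle_genes=cycle,
                   cycle_strength=cycle_strength, seed=seed, **kw)


def _gene_ids(n):
    return [f"G{i:04d}" for i in range(n)]


def _ring_deviations(rng, n_genes_in_cycle, n_case, target):
    """Unit-variance deviations whose adjacent-pair correlation along the
    ring equals ``target`` in expectation, with chords held as weak as the
    construction allows (see module docstring)."""
    L = n_genes_in_cycle
    c1 = np.cos(2 * np.pi / L)
    if c1 < target:
        # latent circle + common factor: corr(d) = a2 + b2*cos(2*pi*d/L)
        a2 = (target - c1) / (1 - c1)
        b2 = 1 - a2
        phi = 2 * np.pi * np.arange(L) / L
        F = rng.standard_normal(n_case)
        A = rng.standard_normal(n_case)
        B = rng.standard_normal(n_case)
        return (np.sqrt(a2) * F
                + np.sqrt(b2) * (np.cos(phi)[:, None] * A
                                 + np.sin(phi)[:, None] * B))
    # wrapped AR(1): corr(d) = (rho^d + rho^(L-d)) / (1 + rho^L)
    from scipy.linalg import cholesky
    from scipy.optimize import brentq
    rho = brentq(
        lambda r: (r + r ** (L - 1)) / (1 + r ** L) - target,
        1e-6, 1 - 1e-9)
    dist = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    C = (rho ** dist + rho ** (L - dist)) / (1 + rho ** L)
    np.fill_diagonal(C, 1.0)
    return cholesky(C, lower=True) @ rng.standard_normal((L, n_case))


def generate_study(spec):
    """Draw one study; returns (StudyCollection, ground-truth dict).

    Deterministic given ``spec.seed``.  Per experiment, every value is
    baseline + group shift + noise, then mapped through the experiment's
    ``scale_factor``/``offset`` so experiments land on incommensurate
    scales without changing their internal structure.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    cycle_pos = {g: i for i, g in enumerate(spec.cycle_genes)}
    experiments = []
    for e_idx, es in enumerate(spec.experiments):
        n_s = es.n_control + es.n_case
        values = spec.baseline + spec.noise_sd * rng.standard_normal(
            (spec.n_genes, n_s))
        case_cols = np.arange(es.n_control, n_s)
        if spec.cycle_genes:
            chain = _ring_deviations(rng, len(spec.cycle_genes),
                                     es.n_case, spec.cycle_strength)
            for g, i in cycle_pos.items():
                values[g, case_cols] = spec.baseline \
                    + spec.noise_sd * chain[i]
        for g, (effect, sign) in spec.de_genes.items():
            values[g, case_cols] += sign * effect * spec.noise_sd
        values = es.scale_factor * values + es.offset
        sample_ids = [f"E{e_idx}C{i}" for i in range(es.n_control)] \
            + [f"E{e_idx}T{i}" for i in range(es.n_case)]
        groups = {s: ("control" if i < es.n_control else "case")
                  for i, s in enumerate(sample_ids)}
        experiments.append(ExpressionExperiment(
            f"exp{e_idx + 1}", list(genes), sample_ids, groups, values))
    truth = {
        "de_genes": {genes[g]: {"effect": eff, "sign": sg}
                     for g, (eff, sg) in spec.de_genes.items()},
        "cycle_genes": [genes[g] for g in spec.cycle_genes],
        "cycle_edges": sorted(
            tuple(sorted((genes[spec.cycle_genes[i]],
                          genes[spec.cycle_genes[(i + 1)
                                                 % len(spec.cycle_genes)]])))
            for i in range(len(spec.cycle_genes))
        ) if spec.cycle_genes else [],
        "seed": spec.seed,
    }
    return intersect_genes(experiments), truth


def recovery_experiment(spec, dea_config=None, deviation_mode=
                        "case_minus_control_mean", time_limit=600.0):
    """Run the full pipeline on one planted study and score recovery.

    Reports the fraction of planted DE genes landing in the first F
    frontiers, whether the optimal tour restricted to the planted-cycle
    genes reproduces the planted ring (checked in every experiment), and
    the recall of planted ring edges among the pairs adjacent in that
    restricted tour in *every* experiment (consensus recall).
    """
    if len(spec.de_genes) < 1 or len(spec.cycle_genes) < 4:
        raise DataValidationError(
            "recovery_experiment needs planted DE genes and a cycle")
    dea_config = dea_config or dea_mod.DEAConfig()
    collection, truth = generate_study(spec)
    crit = criteria_mod.compute_criteria(collection)
    assignment = dea_mod.peel_frontiers(crit, dea_config)
    selected = assignment.selected_genes()
    de_ids = set(truth["de_genes"])
    de_recall = (len(de_ids & set(selected)) / len(de_ids)
                 if de_ids else float("nan"))

    planted = truth["cycle_genes"]
    planted_canon = tsp_mod.canonical_cycle(planted)
    cycle_recovered = True
    reports = []
    for exp in collection.experiments:
        prof = correlation_mod.deviation_profiles(
            exp, collection.common_genes, mode=deviation_mode)
        graph = correlation_mod.abs_pearson_graph(prof)
        sub = graph.subgraph(sorted(planted))
        tour = tsp_mod.solve_exact(tsp_mod.build_model(sub),
                                   time_limit=time_limit)
        if list(tour.node_ids) != planted_canon:
            cycle_recovered = False
        reports.append((exp.experiment_id, tour.adjacency()))
    consensus = reports[0][1]
    for _, adj in reports[1:]:
        consensus = consensus & adj
    planted_edges = {frozenset(p) for p in truth["cycle_edges"]}
    consensus_recall = (len(consensus & planted_edges) / len(planted_edges)
                        if planted_edges else float("nan"))
    return {
        "de_recall": de_recall,
        "cycle_recovered": cycle_recovered,
        "consensus_recall": consensus_recall,
        "n_selected": len(selected),
        "truth": truth,
    }
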