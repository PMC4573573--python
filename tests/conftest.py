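import numpy as np
import pytest

from corrpath.correlation import CorrelationGraph
from corrpath.criteria import CriteriaMatrix, PerformanceMeasureSpec
from corrpath.dea import DEAConfig, pareto_bruteforce, peel_frontiers
from corrpath.io import ExpressionExperiment


def make_criteria(values, directions, gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    specs = [PerformanceMeasureSpec(f"pm{j}", d, "signed_mean_diff", "_")
             for j, d in enumerate(directions)]
    return CriteriaMatrix(list(gene_ids), specs, values)


def random_criteria(rng, max_genes=40, max_measures=4):
    """Random instance with mixed optimization directions guaranteed."""
    n = int(rng.integers(5, max_genes + 1))
    j = int(rng.integers(2, max_measures + 1))
    dirs = [str(rng.choice(["maximize", "minimize"])) for _ in range(j)]
    if len(set(dirs)) == 1:  # force at least one of each direction
        dirs[0] = "maximize" if dirs[1] == "minimize" else "minimize"
    values = rng.uniform(0.5, 10.0, size=(n, j))
    return make_criteria(values, dirs)


def random_graph(rng, n, ids=None):
    r = rng.uniform(0.0, 1.0, size=(n, n))
    w = (r + r.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if ids is None:
        ids = [f"n{i:02d}" for i in range(n)]
    return CorrelationGraph(list(ids), w)


def make_experiment(values, n_control, experiment_id="exp", gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    sample_ids = [f"c{i}" for i in range(n_control)] \
        + [f"t{i}" for i in range(n_samples - n_control)]
    groups = {s: ("control" if i < n_control else "case")
              for i, s in enumerate(sample_ids)}
    return ExpressionExperiment(experiment_id, list(gene_ids), sample_ids,
                                groups, values)


N_DEA_INSTANCES = 100


@pytest.fixture(scope="session")
def dea_random_instances():
    """100 seeded random criteria instances with peeled frontiers and the
    brute-force Pareto oracle, shared by the soundness and peeling
    checks (frontier 1 of the peel *is* the efficient set)."""
    out = []
    config = DEAConfig()
    for i in range(N_DEA_INSTANCES):
        crit = random_criteria(np.random.default_rng(1000 + i))
        assignment = peel_frontiers(crit, config)
        pareto = pareto_bruteforce(crit)
        out.append((crit, assignment, pareto))
    return out
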