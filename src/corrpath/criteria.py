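"""Per-gene performance measures for the multi-criteria screening stage.

Each gene becomes one candidate solution of a discretized multiple-criteria
optimization problem; each configured measure contributes one column with a
declared optimization direction.  The default configuration characterizes a
gene, per experiment, by the magnitude of its case-vs-control mean change
(maximize) and its pooled within-group standard deviation (minimize): a
strongly and consistently shifted gene should stand out on both axes, and
because every measure is computed within a single experiment the columns
may live on arbitrarily different (incommensurate) scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

ESTIMATORS = ("abs_mean_diff", "signed_mean_diff", "pooled_sd", "abs_t_stat")

# direction constraints per estimator; None = either direction allowed
_ALLOWED_DIRECTION = {
    "abs_mean_diff": "maximize",
    "abs_t_stat": "maximize",
    "pooled_sd": "minimize",
    "signed_mean_diff": None,
}


@dataclass(frozen=True)
class PerformanceMeasureSpec:
    """One criterion: an estimator evaluated on one experiment.

    ``direction`` declares whether larger (``"maximize"``) or smaller
    (``"minimize"``) values are better for that measure.
    """

    name: str
    direction: str
    estimator: str
    experiment_id: str

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise DataValidationError(f"unknown estimator '{self.estimator}'")
        if self.direction not in ("maximize", "minimize"):
            raise DataValidationError(f"unknown direction '{self.direction}'")
        allowed = _ALLOWED_DIRECTION[self.estimator]
        if allowed is not None and self.direction != allowed:
            raise DataValidationError(
                f"estimator '{self.estimator}' requires direction '{allowed}'"
            )


@dataclass
class CriteriaMatrix:
    """Genes x measures value matrix with per-column directions."""

    gene_ids: list
    pm_specs: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.pm_specs)):
            raise DataValidationError(
                f"criteria matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.pm_specs)} measures"
            )
        if len(self.pm_specs) < 2:
            raise DataValidationError("need at least 2 performance measures")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("criteria values must be finite")

    @property
    def directions(self):
        return [s.direction for s in self.pm_specs]

    def subset(self, gene_ids):
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [pos[g] for g in gene_ids]
        return CriteriaMatrix(list(gene_ids), self.pm_specs, self.values[rows])


def default_specs(collection):
    """Default measures: per experiment, |mean change| (max) + pooled SD (min)."""
    specs = []
    for exp in collection.experiments:
        specs.append(PerformanceMeasureSpec(
            f"{exp.experiment_id}:abs_mean_diff", "maximize",
            "abs_mean_diff", exp.experiment_id))
        specs.append(PerformanceMeasureSpec(
            f"{exp.experiment_id}:pooled_sd", "minimize",
            "pooled_sd", exp.experiment_id))
    return specs


def _group_stats(values, case_idx, ctrl_idx):
    """Per-gene case/control means and sample variances (ddof=1)."""
    case = values[:, case_idx]
    ctrl = values[:, ctrl_idx]
    return (case.mean(axis=1), ctrl.mean(axis=1),
            case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1),
            case.shape[1], ctrl.shape[1])


def _estimate(estimator, values, case_idx, ctrl_idx):
    m_case, m_ctrl, v_case, v_ctrl, n_case, n_ctrl = _group_stats(
        values, case_idx, ctrl_idx)
    mean_diff = m_case - m_ctrl
    if estimator == "signed_mean_diff":
        return mean_diff
    if estimator == "abs_mean_diff":
        return np.abs(mean_diff)
    pooled = np.sqrt(((n_case - 1) * v_case + (n_ctrl - 1) * v_ctrl)
                     / (n_case + n_ctrl - 2))
    if estimator == "pooled_sd":
        return pooled
    # abs_t_stat; zero pooled SD yields inf here — downstream positivity
    # adjustment resolves it, we only warn.
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_diff) / (pooled * np.sqrt(1.0 / n_case + 1.0 / n_ctrl))
    n_degenerate = int(np.sum(~np.isfinite(t)))
    if n_degenerate:
        logger.warning("abs_t_stat: %d genes with zero pooled SD; "
                       "values set to 0 (flat genes carry no signal)",
                       n_degenerate)
        t[~np.isfinite(t)] = 0.0
    return t


def compute_criteria(collection, specs=None):
    """Evaluate every configured measure for every common gene.

    Column order follows ``specs`` exactly.  When ``specs`` is omitted the
    default two-measure-per-experiment configuration is used.
    """
    if specs is None:
        specs = default_specs(collection)
    specs = list(specs)
    known = {e.experiment_id for e in collection.experiments}
    for s in specs:
        if s.experiment_id not in known:
            raise DataValidationError(
                f"measure '{s.name}' references unknown experiment "
                f"'{s.experiment_id}'"
            )
    genes = list(collection.common_genes)
    cols = []
    for s in specs:
        exp = collection.experiment(s.experiment_id)
        sub = exp.subset_genes(genes)
        cols.append(_estimate(s.estimator, sub.values,
                              sub.case_indices, sub.control_indices))
    return CriteriaMatrix(genes, specs, np.column_stack(cols))


def signed_mean_diffs(collection, genes=None):
    """Signed case-minus-control mean difference per gene and experiment."""
    genes = list(collection.common_genes if genes is None else genes)
    out = {}
    for exp in collection.experiments:
        sub = exp.subset_genes(genes)
        out[exp.experiment_id] = _estimate(
            "signed_mean_diff", sub.values, sub.case_indices,
            sub.control_indices)
    return out


def sign_agreement_filter(collection, genes):
    """Keep genes whose expression change points the same way everywhere.

    A gene passes only if its signed mean difference is strictly nonzero
    and of identical sign in every experiment (a zero difference agrees
    with nothing).  With a single experiment the input is returned
    unchanged with a warning — there is nothing to cross-validate against.
    """
    genes = list(genes)
    if len(collection.experiments) < 2:
        logger.warning("sign_agreement_filter: single experiment, "
                       "returning gene list unchanged")
        return genes
    diffs = signed_mean_diffs(collection, genes)
    signs = np.sign(np.column_stack([diffs[e.experiment_id]
                                     for e in collection.experiments]))
    keep = (signs != 0).all(axis=1) & (signs == signs[:, [0]]).all(axis=1)
    return [g for g, k in zip(genes, keep) if k]
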