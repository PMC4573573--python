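"""Deviation profiles and the complete absolute-Pearson gene graph.

Correlation between genes is measured on *deviation profiles* rather than
raw expression: by default each gene's profile is its expression in every
case sample minus its own control-group mean, so two genes correlate when
their departures from the healthy baseline co-vary across tumors.  The
absolute value is taken because inhibition (negative co-variation) is as
informative a link as excitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

MODES = ("case_minus_control_mean", "group_centered")


@dataclass
class DeviationProfiles:
    experiment_id: str
    gene_ids: list
    profiles: np.ndarray
    mode: str

    def __post_init__(self):
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.shape[0] != len(self.gene_ids):
            raise DataValidationError("one profile row per gene required")
        if self.profiles.shape[1] < 3:
            raise DataValidationError(
                "profiles need >= 3 points for a Pearson correlation")


@dataclass
class CorrelationGraph:
    """Complete undirected graph, edge weight = |Pearson r| in [0, 1].

    The diagonal is unused (held at 0); pairs whose correlation is
    undefined (zero variance) are listed in ``degenerate_pairs`` and
    carry weight 0.
    """

    gene_ids: list
    weights: np.ndarray
    degenerate_pairs: set = field(default_factory=set)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise DataValidationError("weight matrix must be n x n")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise DataValidationError("weight matrix must be symmetric")
        off = self.weights[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise DataValidationError("off-diagonal weights must lie in [0, 1]")

    def weight(self, g, h):
        i = self.gene_ids.index(g)
        j = self.gene_ids.index(h)
        return float(self.weights[i, j])

    def subgraph(self, gene_ids):
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        keep = set(gene_ids)
        degen = {p for p in self.degenerate_pairs if set(p) <= keep}
        return CorrelationGraph(list(gene_ids),
                                self.weights[np.ix_(idx, idx)], degen)


def deviation_profiles(exp, genes=None, mode="case_minus_control_mean"):
    """Per-gene deviation vectors used for pairwise correlation.

    ``case_minus_control_mean`` (default): profile(g) = expression of g in
    each case sample minus g's control mean, in sample order (length =
    number of case samples).  ``group_centered``: every sample minus its
    own group mean, concatenated over all samples — usable when case
    samples are scarce.
    """
    if mode not in MODES:
        raise DataValidationError(f"unknown deviation mode '{mode}'")
    genes = list(exp.gene_ids if genes is None else genes)
    missing = set(genes) - set(exp.gene_ids)
    if missing:
        raise DataValidationError(
            f"genes not in experiment '{exp.experiment_id}': "
            f"{sorted(missing)[:5]}")
    sub = exp.subset_genes(genes)
    case_idx = sub.case_indices
    ctrl_idx = sub.control_indices
    if mode == "case_minus_control_mean":
        if len(case_idx) < 3:
            raise DataValidationError(
                f"'{exp.experiment_id}' has {len(case_idx)} case samples; "
                f"the default deviation mode needs >= 3 — use "
                f"mode='group_centered' or provide more data")
        ctrl_mean = sub.values[:, ctrl_idx].mean(axis=1, keepdims=True)
        prof = sub.values[:, case_idx] - ctrl_mean
    else:
        ctrl = sub.values[:, ctrl_idx]
        case = sub.values[:, case_idx]
        prof = np.column_stack([ctrl - ctrl.mean(axis=1, keepdims=True),
                                case - case.mean(axis=1, keepdims=True)])
    return DeviationProfiles(exp.experiment_id, genes, prof, mode)


def abs_pearson_graph(profiles, method="pearson"):
    """Complete |correlation| graph over the profile rows.

    Zero-variance profiles make the coefficient undefined for every pair
    they touch; such pairs get weight 0 (a flat gene must not abort the
    path search) and are recorded in ``degenerate_pairs``.  ``method``
    may be ``"pearson"`` (default) or ``"spearman"``.
    """
    P = np.asarray(profiles.profiles, dtype=float)
    n = P.shape[0]
    if n < 2:
        raise DataValidationError("graph needs >= 2 genes")
    if method == "spearman":
        from scipy.stats import rankdata
        P = np.apply_along_axis(rankdata, 1, P)
    elif method != "pearson":
        raise DataValidationError(f"unknown correlation method '{method}'")
    sd = P.std(axis=1)
    degenerate_rows = np.where(sd == 0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(P)
    w = np.abs(r)
    w[~np.isfinite(w)] = 0.0
    np.clip(w, 0.0, 1.0, out=w)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    degen = set()
    for i in degenerate_rows:
        for j in range(n):
            if j != i:
                w[i, j] = w[j, i] = 0.0
                degen.add(frozenset((profiles.gene_ids[i],
                                     profiles.gene_ids[j])))
    if degen:
        logger.warning("%d gene pairs with undefined correlation set to "
                       "weight 0", len(degen))
    return CorrelationGraph(list(profiles.gene_ids), w, degen)
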