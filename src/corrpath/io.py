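"""Reading, validating and writing case/control expression experiments.

Expression matrices are TSV files with genes in rows (first column = gene
identifier, header row = sample ids).  A companion labels TSV assigns each
sample to the control or case group.  Values are kept in platform-native
units throughout: experiments from different platforms are deliberately
*not* rescaled, because the downstream efficiency analysis is designed to
cope with incommensurate scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

CONTROL_ALIASES = {"control", "healthy", "normal"}
CASE_ALIASES = {"case", "cancer", "tumor"}

#: duplicate gene-row collapse policies accepted by :func:`read_experiment`
DUPLICATE_POLICIES = ("max_abs_mean", "first", "mean")


@dataclass
class ExpressionExperiment:
    """One case/control gene x sample matrix with group labels.

    Parameters
    ----------
    experiment_id : str
        Free-text identifier (e.g. a GEO accession).
    gene_ids : list of str
        Row identifiers; unique, order preserved.
    sample_ids : list of str
        Column identifiers; unique, order preserved.
    groups : dict
        Maps every sample id to ``"control"`` or ``"case"``.
    values : ndarray of shape (n_genes, n_samples)
        Expression values in platform-native units.
    """

    experiment_id: str
    gene_ids: list
    sample_ids: list
    groups: dict
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError(
                f"{self.experiment_id}: duplicate gene ids after load"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError(
                f"{self.experiment_id}: duplicate sample ids"
            )
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"{self.experiment_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError(
                f"{self.experiment_id}: non-finite values present after load"
            )
        for sid in self.sample_ids:
            if sid not in self.groups:
                raise DataValidationError(
                    f"{self.experiment_id}: sample '{sid}' has no group label"
                )
            if self.groups[sid] not in ("control", "case"):
                raise DataValidationError(
                    f"{self.experiment_id}: sample '{sid}' has invalid group "
                    f"'{self.groups[sid]}'"
                )
        for name, idx in (("control", self.control_indices),
                          ("case", self.case_indices)):
            if len(idx) < 2:
                raise DataValidationError(
                    f"{self.experiment_id}: fewer than 2 {name} samples"
                )

    @property
    def control_indices(self):
        return [i for i, s in enumerate(self.sample_ids)
                if self.groups[s] == "control"]

    @property
    def case_indices(self):
        return [i for i, s in enumerate(self.sample_ids)
                if self.groups[s] == "case"]

    def gene_values(self, gene_id):
        """Row of expression values for one gene."""
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, gene_ids):
        """New experiment restricted to ``gene_ids`` (given order)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [pos[g] for g in gene_ids]
        return ExpressionExperiment(
            self.experiment_id, list(gene_ids), self.sample_ids,
            dict(self.groups), self.values[rows],
        )


@dataclass
class StudyCollection:
    """Several experiments sharing a common gene universe.

    ``common_genes`` is the ordered intersection of all member gene sets;
    no value rescaling is ever performed on intersection.
    """

    experiments: list
    common_genes: list = field(default_factory=list)

    def __post_init__(self):
        for exp in self.experiments:
            missing = set(self.common_genes) - set(exp.gene_ids)
            if missing:
                raise DataValidationError(
                    f"common_genes not contained in experiment "
                    f"'{exp.experiment_id}': missing {sorted(missing)[:5]}"
                )

    def experiment(self, experiment_id):
        for exp in self.experiments:
            if exp.experiment_id == experiment_id:
                return exp
        raise KeyError(experiment_id)


def _normalize_group(raw, sample_id):
    g = str(raw).strip().lower()
    if g in CONTROL_ALIASES:
        return "control"
    if g in CASE_ALIASES:
        return "case"
    raise DataValidationError(
        f"sample '{sample_id}': unrecognized group label '{raw}' "
        f"(accepted: {sorted(CONTROL_ALIASES)} / {sorted(CASE_ALIASES)})"
    )


def read_labels(labels_path):
    """Read a sample_id<TAB>group table into a normalized dict."""
    df = pd.read_csv(labels_path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "group" not in cols:
        raise DataValidationError(
            f"{labels_path}: labels file must have columns sample_id, group"
        )
    df.columns = cols
    return {
        str(r["sample_id"]): _normalize_group(r["group"], r["sample_id"])
        for _, r in df.iterrows()
    }


def read_experiment(matrix_path, labels_path, experiment_id,
                    duplicate_policy="max_abs_mean", missing_policy="error"):
    """Load and validate one expression experiment from TSV files.

    Parameters
    ----------
    matrix_path, labels_path : path-like
        Expression matrix (genes x samples) and sample-label tables.
    experiment_id : str
    duplicate_policy : {"max_abs_mean", "first", "mean"}
        How to collapse duplicated gene-id rows (microarrays often carry
        several probes per gene).  The default keeps the row with the
        highest mean absolute value.
    missing_policy : {"error", "mean"}
        ``"error"`` rejects matrices with missing cells; ``"mean"``
        imputes each gene's row mean (explicit opt-in — imputation can
        move frontier memberships).
    """
    if duplicate_policy not in DUPLICATE_POLICIES:
        raise DataValidationError(f"unknown duplicate policy '{duplicate_policy}'")
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    nonnum = bad.isna() & df.notna()
    if nonnum.to_numpy().any():
        r, c = np.argwhere(nonnum.to_numpy())[0]
        raise DataValidationError(
            f"{matrix_path}: non-numeric cell at gene '{df.index[r]}', "
            f"sample '{df.columns[c]}': {df.iat[r, c]!r}"
        )
    df = bad

    if df.isna().to_numpy().any():
        if missing_policy == "mean":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
            logger.warning("%s: missing values imputed with per-gene means",
                           experiment_id)
        else:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise DataValidationError(
                f"{matrix_path}: missing value at gene '{df.index[r]}', "
                f"sample '{df.columns[c]}' (missing_policy='error')"
            )

    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("%s: %d duplicated gene ids collapsed with policy %s",
                       experiment_id, len(dups), duplicate_policy)
        if duplicate_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        elif duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:  # max_abs_mean
            score = df.abs().mean(axis=1)
            keep = np.zeros(len(df), dtype=bool)
            best = {}
            for i, (g, s) in enumerate(zip(df.index, score)):
                if g not in best or s > score.iloc[best[g]]:
                    best[g] = i
            keep[list(best.values())] = True
            df = df[keep]

    groups = read_labels(labels_path)
    unlabeled = [s for s in df.columns if s not in groups]
    if unlabeled:
        raise DataValidationError(
            f"{labels_path}: sample '{unlabeled[0]}' present in matrix but "
            f"missing from labels file"
        )
    groups = {s: groups[s] for s in df.columns}
    return ExpressionExperiment(
        experiment_id, list(df.index), list(df.columns), groups,
        df.to_numpy(dtype=float),
    )


def write_experiment(exp, matrix_path, labels_path):
    """Write an experiment back to the TSV pair read by :func:`read_experiment`."""
    df = pd.DataFrame(exp.values, index=exp.gene_ids, columns=exp.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.12g")
    lab = pd.DataFrame(
        {"sample_id": exp.sample_ids,
         "group": [exp.groups[s] for s in exp.sample_ids]}
    )
    lab.to_csv(labels_path, sep="\t", index=False)


def intersect_genes(experiments):
    """Build a :class:`StudyCollection` over the common gene universe.

    The intersection order follows the first experiment; values are left
    untouched (units stay incommensurate by design).
    """
    if not experiments:
        raise DataValidationError("intersect_genes requires >= 1 experiment")
    common = set(experiments[0].gene_ids)
    for exp in experiments[1:]:
        common &= set(exp.gene_ids)
    if not common:
        raise DataValidationError(
            "empty gene intersection across experiments: "
            + ", ".join(e.experiment_id for e in experiments)
        )
    ordered = [g for g in experiments[0].gene_ids if g in common]
    return StudyCollection(list(experiments), ordered)


def write_table(rows, path):
    """Write a homogeneous record set as TSV (header always present).

    Floats are serialized with 12 significant digits so write/read round
    trips preserve values to ~1e-12 relative precision.  Row order is
    taken as given (callers pass deterministically ordered records).
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
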