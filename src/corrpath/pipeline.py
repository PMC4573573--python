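"""Two-stage pipeline orchestration over a single run configuration.

Stage 1: read experiments -> intersect gene universes -> per-gene
performance measures -> DEA frontier peeling -> optional cross-experiment
sign-agreement filter -> selected gene list ordered by frontier.

Stage 2: per experiment, deviation profiles -> |Pearson| graph -> exact
TSP tours at growing prefix sizes (stability study) -> cross-experiment
consensus pairs -> optional pathway-membership overlap.

All outputs are TSV/JSON with a run-metadata record so a run is fully
self-describing and byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import correlation, criteria, dea, io, stability
from .exceptions import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    experiments: list                 # [{id, matrix, labels}, ...]
    criteria_specs: list = None       # [{experiment, estimator, direction}]
    epsilon: float = 1e-6
    num_frontiers: int = 10
    score_tol: float = 1e-6
    positivity_delta: float = 1e-6
    sign_filter: bool = True
    deviation_mode: str = "case_minus_control_mean"
    correlation_method: str = "pearson"
    time_limit: float = 3600.0
    step: int = 5
    pathway_table: str = None
    out_dir: str = "corrpath_out"
    seed: int = 0
    duplicate_policy: str = "max_abs_mean"
    missing_policy: str = "error"

    def dea_config(self):
        return dea.DEAConfig(self.epsilon, self.num_frontiers,
                             self.score_tol, self.positivity_delta)

    @classmethod
    def from_yaml(cls, path, **overrides):
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if "experiments" not in raw:
            raise ConfigError(f"{path}: config must list experiments")
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"{path}: unknown config keys {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        for e in cfg.experiments:
            for key in ("id", "matrix", "labels"):
                if key not in e:
                    raise ConfigError(f"experiment entry missing '{key}': {e}")
            for key in ("matrix", "labels"):
                if not os.path.exists(e[key]):
                    raise ConfigError(f"file not found: {e[key]}")
        if cfg.step < 3:
            raise ConfigError("stability step must be >= 3")
        if cfg.time_limit <= 0:
            raise ConfigError("time_limit must be > 0")
        return cfg


def _load_collection(config):
    exps = [io.read_experiment(e["matrix"], e["labels"], e["id"],
                               duplicate_policy=config.duplicate_policy,
                               missing_policy=config.missing_policy)
            for e in config.experiments]
    return io.intersect_genes(exps)


def _parse_specs(config, collection):
    if not config.criteria_specs:
        return criteria.default_specs(collection)
    specs = []
    for s in config.criteria_specs:
        specs.append(criteria.PerformanceMeasureSpec(
            s.get("name", f"{s['experiment']}:{s['estimator']}"),
            s["direction"], s["estimator"], s["experiment"]))
    return specs


def _metadata(config, extra=None):
    meta = {"config": {k: getattr(config, k)
                       for k in config.__dataclass_fields__},
            "deviation_mode": config.deviation_mode}
    meta.update(extra or {})
    return meta


def stage1(config):
    """Differential-expression screening; returns (assignment, selected).

    Writes ``frontiers.tsv`` (per-gene scores + frontier), the ordered
    ``selected_genes.txt`` and stage-1 run metadata into ``out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    collection = _load_collection(config)
    specs = _parse_specs(config, collection)
    crit = criteria.compute_criteria(collection, specs)
    dcfg = config.dea_config()
    scores = dea.dea_efficient_set(crit, dcfg)
    assignment = dea.peel_frontiers(crit, dcfg)
    selected = assignment.selected_genes()
    if config.sign_filter and len(collection.experiments) >= 2:
        kept = set(criteria.sign_agreement_filter(collection, selected))
        selected = [g for g in selected if g in kept]
    rows = [{"gene_id": g,
             "input_score": si, "output_score": so,
             "efficient": bool(e),
             "frontier": (f if f is not None else "none"),
             "selected": g in set(selected)}
            for g, si, so, e, f in zip(
                assignment.gene_ids, scores.input_score,
                scores.output_score, scores.efficient, assignment.frontier)]
    io.write_table(rows, os.path.join(config.out_dir, "frontiers.tsv"))
    with open(os.path.join(config.out_dir, "selected_genes.txt"), "w") as fh:
        fh.write("\n".join(selected) + ("\n" if selected else ""))
    counts = {}
    for f in assignment.frontier:
        key = f if f is not None else "none"
        counts[key] = counts.get(key, 0) + 1
    logger.info("stage1: %d genes selected; per-frontier counts %s",
                len(selected), counts)
    with open(os.path.join(config.out_dir, "stage1_metadata.json"), "w") as fh:
        json.dump(_metadata(config, {
            "n_common_genes": len(collection.common_genes),
            "frontier_counts": {str(k): v for k, v in counts.items()},
            "n_selected": len(selected),
            "measures": [s.name for s in specs],
        }), fh, indent=2, default=str)
    return assignment, selected


def _tour_record(tour):
    return {"nodes": list(tour.node_ids),
            "total_weight": tour.total_weight,
            "optimal": tour.optimal,
            "stats": tour.stats}


def stage2(config, gene_list):
    """Correlation graphs, exact tours, stability and consensus reports."""
    if len(gene_list) < 3:
        raise ConfigError("stage 2 needs >= 3 genes")
    os.makedirs(config.out_dir, exist_ok=True)
    collection = _load_collection(config)
    missing = set(gene_list) - set(collection.common_genes)
    if missing:
        raise ConfigError(
            f"genes not present in all experiments: {sorted(missing)[:5]}")
    reports = []
    for exp in collection.experiments:
        prof = correlation.deviation_profiles(exp, gene_list,
                                              mode=config.deviation_mode)
        graph = correlation.abs_pearson_graph(
            prof, method=config.correlation_method)
        cm = [{"gene_id": g, **{h: graph.weights[i, j]
                                for j, h in enumerate(graph.gene_ids)}}
              for i, g in enumerate(graph.gene_ids)]
        io.write_table(cm, os.path.join(
            config.out_dir, f"correlation_{exp.experiment_id}.tsv"))
        rep = stability.incremental_tours(
            graph, gene_list, step=config.step,
            time_limit=config.time_limit, experiment_id=exp.experiment_id)
        reports.append(rep)
        payload = {
            "experiment_id": exp.experiment_id,
            "sizes": rep.sizes,
            "tours": {str(s): _tour_record(t) for s, t in rep.tours.items()},
            "persistent_pairs": [
                {"pair": list(p), "fraction": fr, "count": c, "eligible": e}
                for p, fr, c, e in stability.persistent_pairs(rep, 0.0)],
            "degenerate_pairs": sorted(sorted(p) for p in
                                       graph.degenerate_pairs),
            "metadata": _metadata(config),
        }
        with open(os.path.join(
                config.out_dir,
                f"stability_{exp.experiment_id}.json"), "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        full = rep.full_size_tour()
        io.write_table(
            [{"from": a, "to": b, "weight": graph.weight(a, b)}
             for a, b in full.edges()],
            os.path.join(config.out_dir, f"tour_{exp.experiment_id}.tsv"))
    result = {"reports": reports}
    if len(reports) >= 2:
        consensus = stability.consensus_pairs(reports)
        pairs = sorted(tuple(sorted(p)) for p in consensus)
        io.write_table(
            [{"gene_a": a, "gene_b": b} for a, b in pairs] or
            pd.DataFrame(columns=["gene_a", "gene_b"]),
            os.path.join(config.out_dir, "consensus_pairs.tsv"))
        result["consensus"] = consensus
        if config.pathway_table:
            table = stability.load_pathway_table(config.pathway_table)
            overlap = stability.pathway_overlap(consensus, table)
            io.write_table(
                [{**r, "shared_pathways": ";".join(r["shared_pathways"])}
                 for r in overlap] or
                pd.DataFrame(columns=["gene_a", "gene_b", "n_shared",
                                      "shared_pathways"]),
                os.path.join(config.out_dir, "pathway_overlap.tsv"))
            result["pathway_overlap"] = overlap
    return result


def run_all(config):
    """Stage 1 followed by Stage 2 on the selected gene list."""
    assignment, selected = stage1(config)
    result = stage2(config, selected)
    result["assignment"] = assignment
    result["selected"] = selected
    return result
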