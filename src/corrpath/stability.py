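"""Incremental-size stability study and cross-experiment consensus.

A single optimal tour says little about robustness: adding genes to the
candidate list can rearrange the whole cycle.  The stability study
therefore solves the exact TSP on growing prefixes of the gene list
(ordered by efficient-frontier rank), records which gene pairs stay
adjacent as the list grows, and separately intersects full-size tour
adjacencies across experiments.  Pairs that persist across sizes — and
across experiments — are the most defensible path segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import DataValidationError
from . import tsp

logger = logging.getLogger(__name__)


def prefix_sizes(n_genes, step=5):
    """Sizes step, 2*step, ... plus the full length if not a multiple."""
    sizes = list(range(step, n_genes + 1, step))
    if not sizes or sizes[-1] != n_genes:
        sizes.append(n_genes)
    return sizes


@dataclass
class StabilityReport:
    experiment_id: str
    sizes: list
    tours: dict                      # size -> Tour
    adjacency: dict                  # size -> set of frozenset pairs
    persistence_count: dict          # pair -> #sizes adjacent
    eligible_count: dict             # pair -> #sizes both endpoints present
    gene_order: list = field(default_factory=list)

    def full_size_tour(self):
        return self.tours[self.sizes[-1]]


def incremental_tours(graph, ordered_genes, step=5, time_limit=3600.0,
                      experiment_id=""):
    """Exact tours on frontier-ordered gene prefixes of increasing size.

    Prefix sizes below 3 (no cycle exists) are skipped with a warning.
    Persistence counts how often a pair was adjacent; eligibility counts
    the sizes at which both endpoints were even present, so
    ``persistence/eligible`` is a fair fraction for late-arriving genes.
    """
    ordered_genes = list(ordered_genes)
    if step < 3:
        raise DataValidationError("stability step must be >= 3")
    missing = set(ordered_genes) - set(graph.gene_ids)
    if missing:
        raise DataValidationError(
            f"ordered genes absent from graph: {sorted(missing)[:5]}")
    sizes = []
    tours = {}
    adjacency = {}
    for s in prefix_sizes(len(ordered_genes), step):
        if s < 3:
            logger.warning("prefix size %d < 3: skipped", s)
            continue
        sub = graph.subgraph(ordered_genes[:s])
        tour = tsp.solve_exact(tsp.build_model(sub), time_limit=time_limit)
        sizes.append(s)
        tours[s] = tour
        adjacency[s] = tour.adjacency()
    persistence = {}
    eligible = {}
    pos = {g: i for i, g in enumerate(ordered_genes)}
    all_pairs = set().union(*adjacency.values()) if adjacency else set()
    for pair in all_pairs:
        a, b = tuple(pair)
        eligible[pair] = sum(
            1 for s in sizes if pos[a] < s and pos[b] < s)
        persistence[pair] = sum(1 for s in sizes if pair in adjacency[s])
    return StabilityReport(experiment_id, sizes, tours, adjacency,
                           persistence, eligible, ordered_genes)


def persistent_pairs(report, min_fraction=1.0):
    """Pairs adjacent in at least ``min_fraction`` of their eligible sizes.

    Returns records sorted by (fraction desc, count desc, pair id), each
    ``(pair_tuple, fraction, count, eligible)``.
    """
    if not report.sizes:
        raise DataValidationError("empty stability report")
    out = []
    for pair, count in report.persistence_count.items():
        elig = report.eligible_count[pair]
        frac = count / elig if elig else 0.0
        if frac >= min_fraction:
            out.append((tuple(sorted(pair)), frac, count, elig))
    out.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return out


def consensus_pairs(reports):
    """Pairs adjacent in the full-size tour of *every* report."""
    if len(reports) < 2:
        raise DataValidationError("consensus needs >= 2 stability reports")
    universes = [frozenset(r.gene_order) for r in reports]
    if len(set(universes)) != 1:
        diff = set().union(*universes) - set.intersection(*map(set, universes))
        raise DataValidationError(
            f"stability reports cover different gene universes; "
            f"non-shared genes: {sorted(diff)[:10]}")
    consensus = reports[0].full_size_tour().adjacency()
    for r in reports[1:]:
        consensus &= r.full_size_tour().adjacency()
    return consensus


def load_pathway_table(path):
    """Local two-column TSV (gene_id<TAB>pathway_id) -> gene -> {pathways}."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise DataValidationError(
                    f"{path}: malformed pathway row at line {lineno}: "
                    f"{line!r}")
            table.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return table


def pathway_overlap(pairs, table):
    """Shared pathway memberships for each adjacent gene pair.

    Genes absent from the table contribute the empty set; pairs sharing
    nothing are still reported (with an empty list), so the output always
    covers every input pair.
    """
    records = []
    for pair in sorted(tuple(sorted(p)) for p in pairs):
        a, b = pair
        shared = sorted(table.get(a, set()) & table.get(b, set()))
        records.append({"gene_a": a, "gene_b": b,
                        "n_shared": len(shared),
                        "shared_pathways": shared})
    return records
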