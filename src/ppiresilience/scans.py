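"""Secondary analyses: single-gene disruption scan and deletion diagnostics.

The scan removes every network gene one at a time and measures the change
in resilience relative to the intact background.  A common-random-numbers
scheme (one random priority per node per replicate, shared across all
sub-networks) keeps the Monte-Carlo noise of each delta small.

The deletion diagnostics ask whether multi-gene deletions differ from
single-gene disruptions in the interaction degree of the genes they remove
and in the circular genomic distance of the interactions they destroy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._rng import derive_seed_sequence
from .core import DisruptionTable, GeneTable, PPINetwork
from .evostats import TestResult, wilcoxon_rank_sum
from .resilience import FailureGrid, _entropy_matrix, _index_edges

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRecord",
    "single_gene_scan",
    "scan_summary",
    "circular_distance",
    "degree_by_mutation_class",
    "removed_interaction_distances",
]


@dataclass(frozen=True)
class ScanRecord:
    background: str
    gene: str
    delta_resilience: float
    degree_in_background: int


def _score_with_keys(
    n_total: int,
    edges_idx: np.ndarray,
    keep: np.ndarray,
    keys_full: np.ndarray,
    K: int,
) -> float:
    """Resilience of the induced subgraph on ``keep`` using shared node keys."""
    n = int(keep.sum())
    if n == 0:
        return 0.0
    remap = np.cumsum(keep) - 1
    if len(edges_idx):
        mask = keep[edges_idx[:, 0]] & keep[edges_idx[:, 1]]
        edges = remap[edges_idx[mask]]
    else:
        edges = edges_idx
    keys = keys_full[:, keep]
    H = _entropy_matrix(n, edges, K, keys.shape[0], seed=0, keys_matrix=keys)
    mean = H.mean(axis=0)
    return float(1.0 - sum(float(v) for v in mean) / K)


def single_gene_scan(
    background: PPINetwork, genes: GeneTable | None, grid: FailureGrid
) -> list[ScanRecord]:
    """Resilience change from disrupting each network gene individually.

    One record per network gene; deltas are R(G - g) - R(G) computed under
    common random numbers (the same per-node removal priorities drive the
    background and every single-gene knockout), so results are
    seed-deterministic and independent of gene iteration order.
    """
    n = background.n_nodes
    if n < 2:
        raise ValueError("single-gene scan needs a background with >= 2 nodes")
    nodes = background.sorted_nodes()
    edges_idx = _index_edges(nodes, background.edges)
    rng = np.random.default_rng(derive_seed_sequence(grid.seed))
    keys_full = rng.random((grid.M, n))
    keep_all = np.ones(n, dtype=bool)
    base = _score_with_keys(n, edges_idx, keep_all, keys_full, grid.K)
    records = []
    for i, gene in enumerate(nodes):
        keep = keep_all.copy()
        keep[i] = False
        score = _score_with_keys(n, edges_idx, keep, keys_full, grid.K)
        records.append(
            ScanRecord(
                background=background.name,
                gene=gene,
                delta_resilience=score - base,
                degree_in_background=background.degree(gene),
            )
        )
    return records


def scan_summary(records: Iterable[ScanRecord], genes: GeneTable | None = None) -> dict:
    """Fraction of genes whose removal increases resilience, by essentiality."""
    recs = list(records)
    if not recs:
        raise ValueError("no scan records")
    deltas = np.array([r.delta_resilience for r in recs])
    out = {
        "n_genes": len(recs),
        "fraction_delta_positive": float((deltas > 0).mean()),
        "mean_delta": float(deltas.mean()),
    }
    if genes is not None:
        ess = np.array([genes.is_essential(r.gene) if r.gene in genes else False for r in recs])
        if ess.any():
            out["fraction_delta_positive_essential"] = float((deltas[ess] > 0).mean())
        if (~ess).any():
            out["fraction_delta_positive_nonessential"] = float((deltas[~ess] > 0).mean())
    return out


def circular_distance(gene_a: str, gene_b: str, genes: GeneTable) -> float:
    """Shorter-arc distance between gene midpoints on the circular chromosome."""
    for g in (gene_a, gene_b):
        if g not in genes:
            raise KeyError(f"unknown gene {g!r}")
    L = genes.chromosome_length
    delta = abs(genes.midpoint(gene_a) - genes.midpoint(gene_b))
    return float(min(delta, L - delta))


def _split_disruption_classes(
    disruptions: DisruptionTable,
) -> tuple[frozenset[str], frozenset[str]]:
    multi = disruptions.multigene_deletion_genes()
    single = disruptions.single_disruption_genes()
    return multi, single


def degree_by_mutation_class(
    ancestor: PPINetwork,
    disruptions: DisruptionTable,
    alternative: str = "two_sided",
) -> tuple[TestResult, pd.DataFrame]:
    """Compare ancestral PPI degree of multi-gene-deletion vs single hits.

    A gene disrupted by both classes appears once in each sample.  Degrees
    are taken in the ancestor network (0 for genes outside it).
    """
    multi, single = _split_disruption_classes(disruptions)
    if not multi or not single:
        raise ValueError(
            "both mutation classes must be non-empty "
            f"(multi-gene: {len(multi)}, single: {len(single)})"
        )
    rows = [
        {"gene": g, "removal_class": "multi_gene", "degree": ancestor.degree(g)}
        for g in sorted(multi)
    ] + [
        {"gene": g, "removal_class": "single_gene", "degree": ancestor.degree(g)}
        for g in sorted(single)
    ]
    table = pd.DataFrame(rows)
    test = wilcoxon_rank_sum(
        table.loc[table["removal_class"] == "multi_gene", "degree"],
        table.loc[table["removal_class"] == "single_gene", "degree"],
        alternative=alternative,
    )
    return test, table


def removed_interaction_distances(
    ancestor: PPINetwork,
    disruptions: DisruptionTable,
    genes: GeneTable,
    alternative: str = "two_sided",
    deletion_precedence: bool = True,
) -> tuple[TestResult, pd.DataFrame]:
    """Circular distances of interactions destroyed by each mutation class.

    An edge is "removed" when at least one endpoint is disrupted; it is
    classed multi_gene when a multi-gene-deletion gene removed it (ties with
    a single-gene hit resolved by ``deletion_precedence``).
    """
    multi, single = _split_disruption_classes(disruptions)
    disrupted = multi | single
    rows = []
    for a, b in sorted(ancestor.edges):
        hit_multi = a in multi or b in multi
        hit_single = a in single or b in single
        if not (hit_multi or hit_single):
            continue
        if hit_multi and hit_single:
            cls = "multi_gene" if deletion_precedence else "single_gene"
        elif hit_multi:
            cls = "multi_gene"
        else:
            cls = "single_gene"
        dist = circular_distance(a, b, genes) if (a in genes and b in genes) else None
        if dist is None:
            logger.debug("edge (%s, %s) endpoint missing from gene table", a, b)
            continue
        rows.append({"gene_a": a, "gene_b": b, "distance": dist, "removal_class": cls})
    if not rows:
        raise ValueError("no removed edges")
    table = pd.DataFrame(rows)
    x = table.loc[table["removal_class"] == "multi_gene", "distance"]
    y = table.loc[table["removal_class"] == "single_gene", "distance"]
    if x.empty or y.empty:
        raise ValueError(
            "both removal classes must destroy at least one interaction "
            f"(multi-gene: {len(x)}, single: {len(y)})"
        )
    test = wilcoxon_rank_sum(x, y, alternative=alternative)
    test.extra["mean_distance_multi_gene"] = float(x.mean())
    test.extra["mean_distance_single_gene"] = float(y.mean())
    return test, table
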