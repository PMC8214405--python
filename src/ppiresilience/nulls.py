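"""Randomized counterpart ensembles for evolved clones.

Two schemes, each size-matched to the number of genes disrupted in the
corresponding evolved clone:

* ``uniform_all`` — genes sampled uniformly without replacement from the
  whole gene table (essential genes included);
* ``weighted_disrupted`` — sampling restricted to genes disrupted in at
  least one population, with per-draw probability proportional to the
  number of distinct populations that disrupted the gene.

Replicates are mutually independent: no phylogenetic nesting across
timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import derive_seed_sequence, spawn_rng
from .core import DisruptionTable, GeneTable, PPINetwork
from .resilience import FailureGrid, RemovalScorer

__all__ = [
    "SCHEMES",
    "DisruptionWeights",
    "compute_population_weights",
    "sample_uniform_null",
    "sample_weighted_null",
    "build_null_ensemble",
]

SCHEMES = ("uniform_all", "weighted_disrupted")


@dataclass(frozen=True)
class DisruptionWeights:
    """Per-gene count of distinct populations with >= 1 disruption."""

    weights: Mapping[str, int]

    @property
    def eligible_genes(self) -> list[str]:
        return sorted(g for g, w in self.weights.items() if w >= 1)

    def weight(self, gene: str) -> int:
        return int(self.weights.get(gene, 0))


def compute_population_weights(disruptions: DisruptionTable) -> DisruptionWeights:
    """w_g = number of distinct populations containing a disruption of g.

    Repeated disruptions within one population count once; genes never
    disrupted get w_g = 0 and are ineligible under the weighted scheme.
    """
    if len(disruptions) == 0:
        raise ValueError("empty disruption table")
    counts = disruptions.frame.groupby("gene")["population"].nunique()
    return DisruptionWeights({str(g): int(w) for g, w in counts.items()})


def _coerce_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return spawn_rng(seed)


def sample_uniform_null(
    genes: GeneTable, n: int, seed: int | np.random.Generator
) -> frozenset[str]:
    """Uniform sample of ``n`` distinct genes from the full gene table."""
    pool = genes.gene_ids
    if n > len(pool):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(pool)}")
    if n == 0:
        return frozenset()
    rng = _coerce_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return frozenset(pool[i] for i in idx)


def sample_weighted_null(
    weights: DisruptionWeights, n: int, seed: int | np.random.Generator
) -> frozenset[str]:
    """Sequential proportional sampling without replacement over w_g >= 1.

    Implemented as an exponential race (keys Exp(1)/w_g, take the n
    smallest), which is distributionally identical to drawing genes one at
    a time with probability proportional to weight among those remaining.
    """
    pool = weights.eligible_genes
    if n > len(pool):
        raise ValueError(
            f"cannot sample {n} genes from {len(pool)} eligible (w >= 1) genes"
        )
    if n == 0:
        return frozenset()
    rng = _coerce_rng(seed)
    w = np.array([weights.weight(g) for g in pool], dtype=float)
    keys = rng.exponential(size=len(pool)) / w
    chosen = np.argpartition(keys, n - 1)[:n]
    return frozenset(pool[i] for i in chosen)


def build_null_ensemble(
    ancestor: PPINetwork,
    genes: GeneTable,
    weights: DisruptionWeights | None,
    clone_sizes: Mapping[str, int],
    scheme: str,
    R: int,
    grid: FailureGrid,
    seed: int = 0,
) -> pd.DataFrame:
    """Resilience of R randomized networks per clone under one scheme.

    Each replicate draws a fresh disruption set of size ``clone_sizes[clone]``,
    prunes it from the ancestor, and scores it with the same failure grid as
    the evolved networks.  Replicate seeds derive from
    (seed, clone, scheme, replicate), so results are independent of clone
    iteration order.  Returns a frame keyed by (clone, scheme, replicate).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "weighted_disrupted" and weights is None:
        raise ValueError("weighted_disrupted scheme requires DisruptionWeights")
    if R < 1:
        raise ValueError("R must be >= 1")
    scorer = RemovalScorer(ancestor, grid)
    rows = []
    for clone in sorted(clone_sizes):
        n = int(clone_sizes[clone])
        for r in range(R):
            rng = spawn_rng(seed, "null", clone, scheme, r)
            if scheme == "uniform_all":
                drawn = sample_uniform_null(genes, n, rng)
            else:
                drawn = sample_weighted_null(weights, n, rng)
            # per-replicate scoring streams keep Monte-Carlo noise
            # independent across replicates; an empty draw keeps the grid's
            # default stream so it scores identically to the ancestor
            score_seq = (
                derive_seed_sequence(grid.seed, "null_score", clone, scheme, r)
                if drawn
                else None
            )
            rows.append(
                {
                    "clone": clone,
                    "scheme": scheme,
                    "replicate": r,
                    "n": n,
                    "resilience": scorer.score(drawn, seed_sequence=score_seq),
                }
            )
    return pd.DataFrame(rows, columns=["clone", "scheme", "replicate", "n", "resilience"])
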