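"""Network resilience under random node failure.

Resilience is 1 minus the mean normalized Shannon entropy of connected
component sizes, averaged over a grid of failure rates f_k = k/K
(k = 0..K-1, f = 1 excluded) and M Monte-Carlo removal replicates.  At
each rate, floor(f*N) nodes are removed uniformly without replacement;
equivalently — and this is how the engine works — each replicate draws one
random removal permutation and the grid rates are checkpoints along it.

Entropy of a remainder with component sizes c_i and N_rem nodes:

    H_norm = [-sum_i (c_i/N_rem) ln(c_i/N_rem)] / ln(N_rem)

with H_norm := 0 when N_rem <= 1 or the remainder is connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_seed_sequence
from .core import PPINetwork, prune_network

__all__ = [
    "FailureGrid",
    "EntropyEstimate",
    "ResilienceScore",
    "component_entropy",
    "failure_curve",
    "resilience_score",
    "RemovalScorer",
    "resilience_of_removal",
    "write_resilience_table",
]


@dataclass(frozen=True)
class FailureGrid:
    """Failure-rate grid and Monte-Carlo settings.

    ``K`` grid steps give rates k/K for k = 0..K-1 (f = 1 excluded);
    ``M`` removal replicates per network; ``seed`` drives all draws.
    """

    K: int = 100
    M: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def rates(self) -> np.ndarray:
        return np.arange(self.K) / self.K


@dataclass(frozen=True)
class EntropyEstimate:
    f: float
    mean_H: float
    se_H: float


@dataclass(frozen=True)
class ResilienceScore:
    value: float
    grid: FailureGrid
    curve: tuple[EntropyEstimate, ...] = field(repr=False)
    network_name: str = "network"


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def _entropy_from_sizes(sizes: Iterable[int], n: int) -> float:
    if n <= 1:
        return 0.0
    h = 0.0
    for c in sizes:
        p = c / n
        h -= p * math.log(p)
    h /= math.log(n)
    return min(max(h, 0.0), 1.0)


def _entropy_checkpoints(
    n: int,
    adjacency: Sequence[Sequence[int]],
    kept_counts: Sequence[int],
    keys: np.ndarray,
) -> dict[int, float]:
    """Entropies at the given surviving-node counts along one removal order.

    Nodes are removed in order of increasing ``keys``; the survivors are
    added back one at a time (largest key first) while a union-find tracks
    component sizes and S = sum_i c_i ln c_i, so each checkpoint entropy is
    H_norm = (ln N_act - S/N_act) / ln N_act in O(1).
    """
    order = np.argsort(keys, kind="stable")
    targets = set(kept_counts)
    out: dict[int, float] = {}
    if 0 in targets:
        out[0] = 0.0
    parent = list(range(n))
    size = [1] * n
    active = bytearray(n)
    S = 0.0
    n_act = 0
    n_comp = 0
    log = math.log
    for pos in range(n - 1, -1, -1):
        v = int(order[pos])
        active[v] = 1
        n_act += 1
        n_comp += 1
        for u in adjacency[v]:
            if not active[u]:
                continue
            # find roots with path halving
            ra = v
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = u
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra == rb:
                continue
            if size[ra] < size[rb]:
                ra, rb = rb, ra
            a, b = size[ra], size[rb]
            S += (a + b) * log(a + b)
            if a > 1:
                S -= a * log(a)
            if b > 1:
                S -= b * log(b)
            parent[rb] = ra
            size[ra] = a + b
            n_comp -= 1
        if n_act in targets:
            if n_act <= 1 or n_comp == 1:
                # <=1 node or a connected remainder: entropy exactly 0
                out[n_act] = 0.0
            else:
                ln_n = log(n_act)
                h = (ln_n - S / n_act) / ln_n
                out[n_act] = min(max(h, 0.0), 1.0)
    return out


def _build_adjacency(n: int, edges: np.ndarray) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _entropy_matrix(
    n: int,
    edges: np.ndarray,
    K: int,
    M: int,
    seed: int,
    keys_matrix: np.ndarray | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
) -> np.ndarray:
    """(M, K) matrix of normalized entropies; replicate m, grid step k.

    If ``keys_matrix`` is given (shape (M, n)), removal orders come from it
    (common-random-numbers mode); otherwise keys are drawn from
    ``seed_sequence`` (falling back to a sequence derived from ``seed``).
    """
    removed = (np.arange(K) * n) // K  # floor(k/K * n)
    kept_counts = (n - removed).tolist()
    adjacency = _build_adjacency(n, edges)
    rng = None
    if keys_matrix is None:
        rng = np.random.default_rng(
            seed_sequence if seed_sequence is not None else derive_seed_sequence(seed)
        )
    H = np.empty((M, K))
    for m in range(M):
        keys = rng.random(n) if keys_matrix is None else keys_matrix[m]
        by_count = _entropy_checkpoints(n, adjacency, kept_counts, keys)
        H[m] = [by_count[c] for c in kept_counts]
    return H


def _index_edges(sorted_nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(sorted_nodes)}
    arr = np.array([[pos[a], pos[b]] for a, b in sorted(edges)], dtype=np.int64)
    return arr.reshape(-1, 2)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def component_entropy(network: PPINetwork) -> float:
    """Normalized Shannon entropy of component sizes (singletons included).

    0 for a connected or <=1-node network; 1 when every node is a singleton
    and N >= 2.
    """
    n = network.n_nodes
    if n <= 1:
        return 0.0
    import networkx as nx

    sizes = [len(c) for c in nx.connected_components(network.to_networkx())]
    if len(sizes) == 1:
        return 0.0
    return _entropy_from_sizes(sizes, n)


def failure_curve(network: PPINetwork, grid: FailureGrid) -> list[EntropyEstimate]:
    """Mean +- SE normalized entropy at every grid failure rate.

    Deterministic given (network node/edge sets, grid); the network name
    does not enter the draws, so identical networks score identically.
    """
    n = network.n_nodes
    if n == 0:
        raise ValueError("cannot compute failure curve of empty network")
    nodes = network.sorted_nodes()
    edges = _index_edges(nodes, network.edges)
    H = _entropy_matrix(n, edges, grid.K, grid.M, grid.seed)
    mean = H.mean(axis=0)
    if grid.M > 1:
        se = H.std(axis=0, ddof=1) / math.sqrt(grid.M)
    else:
        se = np.zeros(grid.K)
    return [
        EntropyEstimate(float(f), float(m), float(s))
        for f, m, s in zip(grid.rates, mean, se)
    ]


def resilience_score(network: PPINetwork, grid: FailureGrid) -> ResilienceScore:
    """1 minus the grid-average of mean entropy; in [0, 1]."""
    curve = failure_curve(network, grid)
    value = 1.0 - sum(e.mean_H for e in curve) / grid.K
    return ResilienceScore(
        value=float(value),
        grid=grid,
        curve=tuple(curve),
        network_name=network.name,
    )


class RemovalScorer:
    """Fast resilience scoring of an ancestor network minus a removal set.

    Produces values identical to
    ``resilience_score(prune_network(ancestor, removed), grid).value``
    without constructing intermediate network objects; used by the null
    ensembles and the pipeline where many removal sets hit one ancestor.
    """

    def __init__(self, ancestor: PPINetwork, grid: FailureGrid):
        self.ancestor = ancestor
        self.grid = grid
        self._nodes = ancestor.sorted_nodes()
        self._pos = {g: i for i, g in enumerate(self._nodes)}
        self._edges = _index_edges(self._nodes, ancestor.edges)

    def score(
        self,
        removed_genes: Iterable[str],
        seed_sequence: np.random.SeedSequence | None = None,
    ) -> float:
        """Score the pruned network.

        With the default ``seed_sequence`` the result is bit-identical to
        pruning and calling :func:`resilience_score` under the same grid.
        Ensemble callers pass per-replicate sequences so that Monte-Carlo
        noise is independent across replicates and averages out.
        """
        removed_idx = {self._pos[g] for g in removed_genes if g in self._pos}
        n_total = len(self._nodes)
        keep = np.ones(n_total, dtype=bool)
        if removed_idx:
            keep[list(removed_idx)] = False
        n = int(keep.sum())
        if n == 0:
            raise ValueError("cannot compute failure curve of empty network")
        remap = np.cumsum(keep) - 1
        if len(self._edges):
            mask = keep[self._edges[:, 0]] & keep[self._edges[:, 1]]
            edges = remap[self._edges[mask]]
        else:
            edges = self._edges
        H = _entropy_matrix(
            n, edges, self.grid.K, self.grid.M, self.grid.seed,
            seed_sequence=seed_sequence,
        )
        # identical summation order to resilience_score, so the fast path is
        # bit-for-bit equal to prune_network + resilience_score
        mean = H.mean(axis=0)
        return float(1.0 - sum(float(v) for v in mean) / self.grid.K)


def resilience_of_removal(
    ancestor: PPINetwork, removed: Iterable[str], grid: FailureGrid
) -> float:
    """Resilience of ``ancestor`` with ``removed`` genes pruned out."""
    return RemovalScorer(ancestor, grid).score(removed)


def write_resilience_table(scores: Iterable[ResilienceScore], path: str | Path) -> None:
    rows = [
        {
            "network_name": s.network_name,
            "resilience": s.value,
            "K": s.grid.K,
            "M": s.grid.M,
            "seed": s.grid.seed,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_failure_curve(score: ResilienceScore, path: str | Path) -> None:
    rows = [
        {"network_name": score.network_name, "f": e.f, "mean_H": e.mean_H, "se_H": e.se_H}
        for e in score.curve
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _check_prune_equivalence(ancestor: PPINetwork, removed: set[str], grid: FailureGrid) -> bool:
    """Internal invariant helper: fast path equals prune-then-score."""
    direct = resilience_score(prune_network(ancestor, removed), grid).value
    fast = RemovalScorer(ancestor, grid).score(removed)
    return math.isclose(direct, fast, rel_tol=0, abs_tol=0) or direct == fast
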