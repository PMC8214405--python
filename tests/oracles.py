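"""Independent brute-force oracles used to verify the package's fast paths.

Everything here recomputes expectations from first principles — exhaustive
subset enumeration for the failure-entropy curve, 2^n sign vectors for the
signed-rank test, rank-split enumeration for the rank-sum test and
fixed-margin table enumeration for Fisher's test — deliberately sharing no
code with the implementations under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import rankdata


def entropy_norm(sizes, n) -> float:
    """Normalized component-size entropy computed directly from the formula."""
    if n <= 1 or len(sizes) == 1:
        return 0.0
    h = -sum((c / n) * math.log(c / n) for c in sizes)
    return h / math.log(n)


def graph_entropy(graph: nx.Graph) -> float:
    sizes = [len(c) for c in nx.connected_components(graph)]
    return entropy_norm(sizes, graph.number_of_nodes())


def exact_mean_entropy(graph: nx.Graph, n_removed: int) -> float:
    """Average entropy over ALL removal subsets of the given size."""
    nodes = sorted(graph.nodes)
    total, count = 0.0, 0
    for removed in combinations(nodes, n_removed):
        rest = graph.copy()
        rest.remove_nodes_from(removed)
        total += graph_entropy(rest)
        count += 1
    return total / count


def exact_failure_curve(graph: nx.Graph, K: int) -> list[float]:
    n = graph.number_of_nodes()
    return [exact_mean_entropy(graph, (k * n) // K) for k in range(K)]


def exact_resilience(graph: nx.Graph, K: int) -> float:
    curve = exact_failure_curve(graph, K)
    return 1.0 - sum(curve) / K


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def signed_rank_brute(differences, alternative: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for mask in range(2**n):
        signs = [(mask >> i) & 1 for i in range(n)]
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    eps = 1e-9
    p_ge = float((stats >= w_obs - eps).mean())
    p_le = float((stats <= w_obs + eps).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_brute(x, y, alternative: str) -> float:
    """Exact rank-sum p by enumerating all assignments of pooled ranks to x.

    Assumes a tie-free pooled sample.  Works on the Mann-Whitney U statistic
    of x so it is directly comparable with the implementation's output.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for positions in combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(positions) - n1 * (n1 + 1) / 2)
    us = np.asarray(us, dtype=float)
    eps = 1e-9
    p_ge = float((us >= u_obs - eps).mean())
    p_le = float((us <= u_obs + eps).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_brute(table, alternative: str) -> float:
    """Exact Fisher p by enumerating every table with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {k: prob(k) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return float(sum(p for k, p in probs.items() if k >= a))
    if alternative == "less":
        return float(sum(p for k, p in probs.items() if k <= a))
    p_obs = probs[a]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= p_obs)))
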