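"""Statistical layer: per-population resilience slopes and hypothesis tests.

The headline comparison is a paired, exact Wilcoxon signed-rank test of the
per-population evolved slope against the mean slope of that population's
randomized replicate series.  Populations are the unit of replication, so
the exact small-sample null (all 2^n sign assignments) matters and is
implemented here directly; rank-sum, binomial, Fisher and Pearson tests
delegate to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALTERNATIVES",
    "SlopeEstimate",
    "TestResult",
    "ols_slope",
    "wilcoxon_signed_rank_exact",
    "paired_resilience_test",
    "wilcoxon_rank_sum",
    "binomial_tail",
    "fisher_exact_2x2",
    "pearson_correlation",
    "write_test_results",
    "write_slopes",
]

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS rate of change of resilience per generation for one series."""

    population: str
    series: str
    slope: float
    intercept: float
    n_points: int


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alternative: str
    n: int
    method: str = "exact"
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(
            f"alternative {alternative!r} not one of {ALTERNATIVES}"
        )
    return alternative


# ---------------------------------------------------------------------------
# Slopes
# ---------------------------------------------------------------------------


def ols_slope(
    points: Iterable[tuple[float, float]],
    population: str = "",
    series: str = "evolved",
) -> SlopeEstimate:
    """Ordinary least-squares slope of resilience against generation."""
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all generations identical; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)
    return SlopeEstimate(population, series, slope, intercept, len(pts))


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_distribution(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Counts of sign assignments by doubled positive-rank sum.

    Ranks are doubled so tied (half-integer average) ranks become integers;
    counts fit exactly in float64 for n <= 25 (2^25 < 2^53).
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(
    differences: Iterable[float], alternative: str = "greater"
) -> TestResult:
    """Exact signed-rank test from the full 2^n sign-assignment null.

    Zero differences are dropped before ranking; tied absolute differences
    receive average ranks.  The statistic is W+ (sum of ranks of positive
    differences).  Exact enumeration regime: 1 <= n <= 25 after zeros.
    """
    _check_alternative(alternative)
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise ValueError("no differences provided")
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    n = int(d.size)
    if n > 25:
        raise ValueError(f"n = {n} exceeds the exact enumeration regime (n <= 25)")
    ranks = stats.rankdata(np.abs(d))
    doubled = np.rint(2.0 * ranks).astype(int)
    w_plus = float(ranks[d > 0].sum())
    w2 = int(round(2.0 * w_plus))
    counts = _signed_rank_distribution(doubled.tolist())
    denom = 2.0**n
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(
        test_name="wilcoxon_signed_rank_exact",
        statistic=w_plus,
        p_value=float(p),
        alternative=alternative,
        n=n,
        method="exact_enumeration",
    )


def paired_resilience_test(
    evolved_slopes: Mapping[str, float],
    null_slopes: Mapping[str, float | Iterable[float]],
    scheme: str = "uniform_all",
    alternative: str = "greater",
) -> TestResult:
    """Exact signed-rank test of evolved vs null slope, paired by population.

    For each population the difference is (evolved slope) minus the mean of
    that population's null replicate slopes; ``null_slopes`` values may be
    scalars (already summarized) or iterables of replicate slopes.  The
    default alternative "greater" asks whether evolved networks lose
    resilience more slowly than their randomized counterparts.
    """
    if set(evolved_slopes) != set(null_slopes):
        missing = set(evolved_slopes) ^ set(null_slopes)
        raise ValueError(f"population sets differ between series: {sorted(missing)}")
    if not evolved_slopes:
        raise ValueError("no populations provided")
    diffs = []
    for pop in sorted(evolved_slopes):
        null_val = null_slopes[pop]
        if np.isscalar(null_val):
            summary = float(null_val)
        else:
            arr = np.asarray(list(null_val), dtype=float)
            if arr.size == 0:
                raise ValueError(f"population {pop!r} has no null replicate slopes")
            summary = float(arr.mean())
        diffs.append(float(evolved_slopes[pop]) - summary)
    result = wilcoxon_signed_rank_exact(diffs, alternative=alternative)
    return TestResult(
        test_name=f"paired_resilience_signed_rank[{scheme}]",
        statistic=result.statistic,
        p_value=result.p_value,
        alternative=alternative,
        n=len(diffs),
        method=result.method,
        extra={"scheme": scheme},
    )


# ---------------------------------------------------------------------------
# Rank-sum, binomial, Fisher, Pearson
# ---------------------------------------------------------------------------

_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def wilcoxon_rank_sum(
    x: Iterable[float], y: Iterable[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann-Whitney / Wilcoxon rank-sum test with average ranks for ties.

    Exact enumeration over all rank splits (ties handled through average
    ranks) when both samples have <= 10 values; otherwise a tie-corrected
    normal approximation, with the regime recorded in ``method``.
    """
    _check_alternative(alternative)
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = int(xa.size), int(ya.size)
    offset = n1 * (n1 + 1) / 2.0
    if n1 <= 10 and n2 <= 10:
        from itertools import combinations

        ranks = stats.rankdata(np.concatenate([xa, ya]))
        u_obs = float(ranks[:n1].sum() - offset)
        us = np.fromiter(
            (ranks[list(c)].sum() - offset for c in combinations(range(n1 + n2), n1)),
            dtype=float,
        )
        eps = 1e-9
        p_ge = float((us >= u_obs - eps).mean())
        p_le = float((us <= u_obs + eps).mean())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        statistic, method = u_obs, "exact_enumeration"
    else:
        res = stats.mannwhitneyu(
            xa, ya, alternative=_SCIPY_ALT[alternative], method="asymptotic"
        )
        statistic, p, method = float(res.statistic), float(res.pvalue), "normal_approximation"
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=statistic,
        p_value=float(p),
        alternative=alternative,
        n=n1 + n2,
        method=method,
        extra={"n_x": n1, "n_y": n2},
    )


def binomial_tail(
    x: int, n: int, p0: float, alternative: str = "less"
) -> TestResult:
    """Exact binomial tail probability for x successes in n trials."""
    _check_alternative(alternative)
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"null probability {p0} outside [0, 1]")
    res = stats.binomtest(int(x), int(n), float(p0), alternative=_SCIPY_ALT[alternative])
    return TestResult(
        test_name="binomial_tail",
        statistic=float(x),
        p_value=float(res.pvalue),
        alternative=alternative,
        n=int(n),
        method="exact",
        extra={"p0": float(p0)},
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], alternative: str = "greater"
) -> TestResult:
    """Fisher's exact test on a 2x2 count table."""
    _check_alternative(alternative)
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    if not np.array_equal(arr, arr.astype(int)):
        raise ValueError("non-integer counts in contingency table")
    odds, p = stats.fisher_exact(arr.astype(int), alternative=_SCIPY_ALT[alternative])
    return TestResult(
        test_name="fisher_exact_2x2",
        statistic=float(odds) if math.isfinite(odds) else float("inf"),
        p_value=float(p),
        alternative=alternative,
        n=int(arr.sum()),
        method="exact",
        extra={"table": arr.astype(int).tolist()},
    )


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Pearson's r with a two-sided p-value via the t transform."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 points for a correlation test")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValueError("zero variance in correlation input")
    res = stats.pearsonr(xa, ya)
    return TestResult(
        test_name="pearson_correlation",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative="two_sided",
        n=int(xa.size),
        method="t_transform",
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_test_results(results: Iterable[TestResult], path) -> None:
    rows = [
        {
            "test_name": r.test_name,
            "scheme": r.extra.get("scheme", ""),
            "statistic": r.statistic,
            "p_value": r.p_value,
            "alternative": r.alternative,
            "n": r.n,
            "method": r.method,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_slopes(slopes: Iterable[SlopeEstimate], path) -> None:
    rows = [
        {
            "population": s.population,
            "series": s.series,
            "slope": s.slope,
            "intercept": s.intercept,
            "n_points": s.n_points,
        }
        for s in slopes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
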