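"""End-to-end orchestration of the resilience-evolution analysis.

``run_full_analysis`` wires the modules into the full analysis graph:
evolved-network resilience per clone, null ensembles under both
randomization schemes, per-population slopes, exact paired comparisons,
the fitness correlation, deletion diagnostics, essentiality tests and the
optional single-gene scan.  One failure grid is used for every network in
a run and recorded, with seeds and input digests, in a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DisruptionTable, GeneTable, PPINetwork
from .evostats import (
    SlopeEstimate,
    TestResult,
    binomial_tail,
    fisher_exact_2x2,
    ols_slope,
    paired_resilience_test,
    pearson_correlation,
    wilcoxon_rank_sum,
    write_slopes,
    write_test_results,
)
from .nulls import SCHEMES, build_null_ensemble, compute_population_weights
from .resilience import FailureGrid, RemovalScorer
from .scans import (
    degree_by_mutation_class,
    removed_interaction_distances,
    scan_summary,
    single_gene_scan,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for CLI reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    K: int = 10
    M: int = 10
    R: int = 20
    seed: int = 0
    schemes: tuple[str, ...] = SCHEMES
    alternative: str = "greater"
    #: size null sets by all disrupted genes ("all_disrupted") or only those
    #: present in the network ("network_only")
    size_from: str = "all_disrupted"
    #: per-population null summary: mean of replicate slopes
    #: ("mean_of_slopes") or slope of replicate means ("slope_of_means")
    null_summary: str = "mean_of_slopes"
    run_scan: bool = False

    def __post_init__(self) -> None:
        if self.size_from not in ("all_disrupted", "network_only"):
            raise ValueError(f"unknown size_from {self.size_from!r}")
        if self.null_summary not in ("mean_of_slopes", "slope_of_means"):
            raise ValueError(f"unknown null_summary {self.null_summary!r}")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")


def _digest(obj: object) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(sep="\t", index=False).encode()
    else:
        payload = repr(obj).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _clone_sizes(
    disruptions: DisruptionTable, network: PPINetwork, size_from: str
) -> dict[str, int]:
    by_clone = disruptions.genes_by_clone()
    if size_from == "network_only":
        return {c: len(gs & network.nodes) for c, gs in by_clone.items()}
    return {c: len(gs) for c, gs in by_clone.items()}


def _evolved_resilience(
    network: PPINetwork,
    disruptions: DisruptionTable,
    grid: FailureGrid,
) -> pd.DataFrame:
    scorer = RemovalScorer(network, grid)
    by_clone = disruptions.genes_by_clone()
    index = disruptions.clone_index()
    rows = []
    for rec in index.to_dict("records"):
        clone = rec["clone"]
        removed = by_clone.get(clone, frozenset())
        outside = len(removed - network.nodes)
        rows.append(
            {
                "population": rec["population"],
                "generation": rec["generation"],
                "clone": clone,
                "n_disrupted": rec["n_disrupted"],
                "n_outside_network": outside,
                "resilience": scorer.score(removed),
            }
        )
    return pd.DataFrame(rows)


def _complete_clone_grid(
    evolved: pd.DataFrame, disruptions: DisruptionTable, ancestor_value: float
) -> pd.DataFrame:
    """Clones with zero disruptions have no table rows; give them the
    ancestor's resilience so every (population, generation) is represented."""
    # Zero-disruption clones are only reconstructible when the disruption
    # table names the population/generation grid; clones absent entirely
    # (e.g. generation 0) are synthesized per population at missing
    # generations with the ancestral value.
    pops = sorted(set(evolved["population"]) | set(disruptions.frame["population"]))
    gens = sorted(set(evolved["generation"]) | set(disruptions.frame["generation"]))
    rows = []
    have = {(r["population"], r["generation"]) for r in evolved.to_dict("records")}
    for pop in pops:
        for gen in gens:
            if (pop, gen) not in have:
                rows.append(
                    {
                        "population": pop,
                        "generation": gen,
                        "clone": f"{pop}:{gen}:ancestral",
                        "n_disrupted": 0,
                        "n_outside_network": 0,
                        "resilience": ancestor_value,
                    }
                )
    if rows:
        evolved = pd.concat([evolved, pd.DataFrame(rows)], ignore_index=True)
    return evolved.sort_values(["population", "generation", "clone"]).reset_index(drop=True)


def _null_slopes(
    nulls: pd.DataFrame,
    clone_meta: pd.DataFrame,
    ancestor_value: float,
    summary: str,
) -> tuple[dict[str, list[float]], list[SlopeEstimate]]:
    """Per-population replicate slopes for one scheme's null ensemble."""
    merged = nulls.merge(clone_meta, on="clone", how="left")
    per_pop: dict[str, list[float]] = {}
    estimates: list[SlopeEstimate] = []
    scheme = nulls["scheme"].iloc[0] if len(nulls) else "?"
    for pop, grp in merged.groupby("population"):
        rep_slopes = []
        for rep, reps in grp.groupby("replicate"):
            pts = list(zip(reps["generation"], reps["resilience"]))
            if len({g for g, _ in pts}) < 2:
                continue
            rep_slopes.append(ols_slope(pts, population=str(pop), series=str(scheme)).slope)
        if not rep_slopes:
            raise PipelineError("slopes", f"population {pop!r} has <2 null generations")
        per_pop[str(pop)] = rep_slopes
        if summary == "mean_of_slopes":
            value = float(np.mean(rep_slopes))
        else:
            means = grp.groupby("generation")["resilience"].mean()
            value = ols_slope(list(means.items()), population=str(pop)).slope
        estimates.append(
            SlopeEstimate(
                population=str(pop),
                series=str(scheme),
                slope=value,
                intercept=float("nan"),
                n_points=len(rep_slopes),
            )
        )
    return per_pop, estimates


def paired_scheme_p(
    network: PPINetwork,
    genes: GeneTable,
    disruptions: DisruptionTable,
    scheme: str = "uniform_all",
    K: int = 5,
    M: int = 4,
    R: int = 5,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """Paired evolved-vs-null p-value for one scheme, nothing written.

    The reduced path behind the full pipeline's headline test: evolved
    per-clone resilience, one null ensemble, per-population OLS slopes and
    the exact signed-rank comparison.  Used for simulation-based
    calibration where running the full report would be wasteful.
    """
    grid = FailureGrid(K=K, M=M, seed=seed)
    scorer = RemovalScorer(network, grid)
    ancestor_value = scorer.score(frozenset())
    by_clone = disruptions.genes_by_clone()
    clone_index = disruptions.clone_index()
    pops = sorted(set(disruptions.frame["population"]))
    gens = sorted(set(disruptions.frame["generation"]))
    evolved_pts: dict[str, list[tuple[int, float]]] = {p: [] for p in pops}
    for rec in clone_index.to_dict("records"):
        value = scorer.score(by_clone[rec["clone"]])
        evolved_pts[str(rec["population"])].append((int(rec["generation"]), value))
    # (population, generation) cells with no disrupted clones sit at the
    # ancestral resilience on both sides of the comparison
    missing: list[tuple[str, int]] = []
    for pop in pops:
        have = {g for g, _ in evolved_pts[pop]}
        for gen in gens:
            if gen not in have:
                missing.append((pop, gen))
                evolved_pts[pop].append((gen, ancestor_value))
    evolved_slopes = {
        pop: ols_slope(pts, population=pop).slope for pop, pts in evolved_pts.items()
    }
    weights = compute_population_weights(disruptions)
    sizes = {c: len(g) for c, g in by_clone.items()}
    ensemble = build_null_ensemble(
        network, genes, weights, sizes, scheme, R, grid, seed
    )
    meta = clone_index[["clone", "population", "generation"]]
    if missing:
        extra_rows = []
        extra_meta = []
        for pop, gen in missing:
            clone = f"{pop}:{gen}:ancestral"
            extra_meta.append({"clone": clone, "population": pop, "generation": gen})
            for r in range(R):
                extra_rows.append(
                    {"clone": clone, "scheme": scheme, "replicate": r,
                     "n": 0, "resilience": ancestor_value}
                )
        ensemble = pd.concat([ensemble, pd.DataFrame(extra_rows)], ignore_index=True)
        meta = pd.concat([meta, pd.DataFrame(extra_meta)], ignore_index=True)
    per_pop, _ = _null_slopes(ensemble, meta, ancestor_value, "mean_of_slopes")
    return paired_resilience_test(
        evolved_slopes, per_pop, scheme=scheme, alternative=alternative
    ).p_value


def run_full_analysis(
    network: PPINetwork,
    genes: GeneTable,
    disruptions: DisruptionTable,
    outdir: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
    fitness: pd.DataFrame | None = None,
    parallel_genes: frozenset[str] | None = None,
) -> dict:
    """Run the full analysis and write report tables to ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    grid, seeds, input digests and produced outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = FailureGrid(K=config.K, M=config.M, seed=config.seed)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "grid": {"K": grid.K, "M": grid.M, "seed": grid.seed},
        "inputs": {
            "network": _digest(pd.DataFrame(sorted(network.edges))),
            "genes": _digest(genes.frame.reset_index()),
            "disruptions": _digest(disruptions.frame),
        },
        "outputs": [],
        "log": {},
    }
    tests: list[TestResult] = []
    slopes: list[SlopeEstimate] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    # --- evolved resilience -------------------------------------------------
    try:
        scorer = RemovalScorer(network, grid)
        ancestor_value = scorer.score(frozenset())
        evolved = _evolved_resilience(network, disruptions, grid)
        evolved = _complete_clone_grid(evolved, disruptions, ancestor_value)
        _write(evolved, "evolved_resilience.tsv")
        manifest["log"]["ancestor_resilience"] = ancestor_value
        manifest["log"]["n_clones"] = int(evolved["clone"].nunique())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("evolved_resilience", str(exc)) from exc

    # --- evolved slopes -----------------------------------------------------
    try:
        evolved_slopes: dict[str, float] = {}
        for pop, grp in evolved.groupby("population"):
            est = ols_slope(
                list(zip(grp["generation"], grp["resilience"])),
                population=str(pop),
                series="evolved",
            )
            evolved_slopes[str(pop)] = est.slope
            slopes.append(est)
    except Exception as exc:
        raise PipelineError("evolved_slopes", str(exc)) from exc

    # --- null ensembles & paired tests -------------------------------------
    clone_meta = evolved[["clone", "population", "generation"]]
    sizes = _clone_sizes(disruptions, network, config.size_from)
    for clone in clone_meta["clone"]:
        sizes.setdefault(clone, 0)
    weights = compute_population_weights(disruptions) if len(disruptions) else None
    null_frames = []
    for scheme in config.schemes:
        try:
            ensemble = build_null_ensemble(
                ancestor=network,
                genes=genes,
                weights=weights,
                clone_sizes=sizes,
                scheme=scheme,
                R=config.R,
                grid=grid,
                seed=config.seed,
            )
            null_frames.append(ensemble)
            per_pop, null_estimates = _null_slopes(
                ensemble, clone_meta, ancestor_value, config.null_summary
            )
            slopes.extend(null_estimates)
            summarized = (
                {p: float(np.mean(v)) for p, v in per_pop.items()}
                if config.null_summary == "mean_of_slopes"
                else {e.population: e.slope for e in null_estimates if e.series == scheme}
            )
            tests.append(
                paired_resilience_test(
                    evolved_slopes,
                    summarized,
                    scheme=scheme,
                    alternative=config.alternative,
                )
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"nulls[{scheme}]", str(exc)) from exc
    if null_frames:
        nulls_df = pd.concat(null_frames, ignore_index=True).merge(
            clone_meta, on="clone", how="left"
        )
        _write(
            nulls_df[
                ["population", "generation", "clone", "scheme", "replicate", "n", "resilience"]
            ],
            "null_resilience.tsv",
        )

    # --- fitness correlation ------------------------------------------------
    if fitness is not None:
        try:
            mean_res = (
                evolved.groupby(["population", "generation"])["resilience"]
                .mean()
                .reset_index()
            )
            merged = mean_res.merge(fitness, on=["population", "generation"], how="inner")
            if len(merged) >= 3:
                corr = pearson_correlation(merged["fitness"], merged["resilience"])
                corr.extra["scheme"] = "fitness_vs_resilience"
                tests.append(corr)
                _write(merged, "fitness_resilience.tsv")
        except Exception as exc:
            raise PipelineError("fitness_correlation", str(exc)) from exc

    # --- deletion diagnostics ----------------------------------------------
    final_gen = max(disruptions.generations) if len(disruptions) else None
    if final_gen is not None:
        final = disruptions.at_generation(final_gen)
        try:
            test, table = degree_by_mutation_class(network, final)
            test.extra["scheme"] = "degree_by_class"
            tests.append(test)
            _write(table, "degree_by_class.tsv")
        except ValueError as exc:
            manifest["log"]["degree_by_class"] = f"skipped: {exc}"
        try:
            test, table = removed_interaction_distances(network, final, genes)
            test.extra["scheme"] = "interaction_distances"
            tests.append(test)
            _write(table, "interaction_distances.tsv")
        except ValueError as exc:
            manifest["log"]["interaction_distances"] = f"skipped: {exc}"

    # --- essentiality diagnostics ------------------------------------------
    try:
        essential = genes.essential_genes
        if essential and len(essential) < len(genes):
            deg_e = [network.degree(g) for g in sorted(essential)]
            deg_n = [network.degree(g) for g in genes.gene_ids if g not in essential]
            t = wilcoxon_rank_sum(deg_e, deg_n, alternative="greater")
            t.extra["scheme"] = "essential_ppi_enrichment"
            tests.append(t)
        if final_gen is not None and len(disruptions.at_generation(final_gen)):
            final = disruptions.at_generation(final_gen)
            hits = final.frame[["population", "gene"]].drop_duplicates()
            x = int(hits["gene"].isin(essential).sum())
            n = int(len(hits))
            len_e = sum(genes.length(g) for g in essential)
            len_all = int(genes.frame["length"].sum())
            t = binomial_tail(x, n, len_e / len_all, alternative="less")
            t.extra["scheme"] = "essential_disruption_deficit"
            tests.append(t)
        if parallel_genes is not None:
            par = frozenset(parallel_genes)
            a = len(par & essential)
            b = len(essential - par)
            c = len(par - essential)
            d = len(genes) - a - b - c
            t = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
            t.extra["scheme"] = "essential_parallelism"
            tests.append(t)
    except PipelineError:
        raise
    except ValueError as exc:
        manifest["log"]["essentiality"] = f"skipped: {exc}"

    # --- optional single-gene scan -----------------------------------------
    if config.run_scan:
        try:
            records = single_gene_scan(network, genes, grid)
            scan_df = pd.DataFrame(
                {
                    "background": [r.background for r in records],
                    "gene": [r.gene for r in records],
                    "delta_resilience": [r.delta_resilience for r in records],
                    "degree_in_background": [r.degree_in_background for r in records],
                }
            )
            _write(scan_df, "single_gene_scan.tsv")
            manifest["log"]["scan_summary"] = scan_summary(records, genes)
        except Exception as exc:
            raise PipelineError("single_gene_scan", str(exc)) from exc

    # --- report tables ------------------------------------------------------
    write_slopes(slopes, outdir / "slopes.tsv")
    manifest["outputs"].append("slopes.tsv")
    write_test_results(tests, outdir / "tests.tsv")
    manifest["outputs"].append("tests.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["outputs"].append("manifest.json")
    return manifest
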