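"""Synthetic experiments with the statistical structure the analysis assumes.

Generates an interactome, a circular gene table, twelve independently
evolving populations whose lineages accumulate gene disruptions between
timepoints, and saturating fitness trajectories.  Selection is modeled as
degree-biased disruption sampling (exponent ``selection_gamma``) plus
probabilistic rejection of essential-gene disruptions
(``essential_protection``) — not as direct optimization of resilience.

Disruption rates are order-of-magnitude placeholders: the real experiment
publishes no per-population rate estimates, so defaults are chosen only to
give non-trivial disruption counts at the simulated scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ._rng import spawn_rng
from .core import (
    DisruptionTable,
    GeneTable,
    PPINetwork,
    write_disruptions,
    write_edge_list,
    write_gene_table,
)

__all__ = [
    "PopulationConfig",
    "SimulationConfig",
    "SimulatedExperiment",
    "generate_network",
    "generate_gene_table",
    "simulate_disruption_history",
    "simulate_fitness",
    "generate_experiment",
]

_SINGLE_CLASSES = ("nonsense_snp", "small_indel", "mob_insertion")


@dataclass(frozen=True)
class PopulationConfig:
    """One population: disruption rate per 5,000 generations and modifiers.

    ``mutator`` multiplies the overall disruption rate; ``mob_burst``
    multiplies the rate of additional mobile-element insertions (the
    transposon-burst analog), on top of the base process.
    """

    label: str
    rate_per_5k: float = 1.0
    mutator: float = 1.0
    mob_burst: float = 1.0


def _default_populations() -> tuple[PopulationConfig, ...]:
    # six populations at the ancestral rate (first one with a transposon
    # burst), six mutators at an elevated rate
    pops = []
    for i in range(1, 7):
        burst = 4.0 if i == 1 else 1.0
        pops.append(PopulationConfig(f"p{i:02d}", rate_per_5k=1.2, mob_burst=burst))
    for i in range(7, 13):
        pops.append(PopulationConfig(f"p{i:02d}", rate_per_5k=1.2, mutator=4.0))
    return tuple(pops)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 240
    n_network_genes: int = 200
    chromosome_length: int = 600_000
    network_model: str = "duplication_divergence"
    dd_attach_p: float = 0.35
    dd_retain_q: float = 0.45
    er_edge_p: float = 0.02
    pa_m: int = 2
    essential_fraction: float = 0.13
    essential_enrichment: float = 3.0
    populations: tuple[PopulationConfig, ...] = field(default_factory=_default_populations)
    selection_gamma: float = 0.0
    essential_protection: float = 0.0
    deletion_block_rate: float = 0.05
    block_size_mean: float = 3.0
    timepoints: tuple[int, ...] = tuple(range(0, 50_001, 5_000))
    clones_per_timepoint: int = 2
    clone_private_rate: float = 0.3
    fitness_b: float = 0.3
    fitness_c: float = 0.001
    fitness_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_network_genes:
            raise ValueError("n_genes must be >= n_network_genes")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ValueError("essential_fraction must be in [0, 1]")
        if self.selection_gamma < 0:
            raise ValueError("selection_gamma must be >= 0")
        if not (0.0 <= self.essential_protection <= 1.0):
            raise ValueError("essential_protection must be in [0, 1]")
        for p in self.populations:
            if p.rate_per_5k < 0 or p.mutator < 0 or p.mob_burst < 0:
                raise ValueError(f"negative rate parameters for population {p.label}")
        if self.block_size_mean < 2 and self.deletion_block_rate > 0:
            raise ValueError("block_size_mean must be >= 2 when blocks are enabled")

    @classmethod
    def test_scale(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Reduced configuration: minutes-scale end-to-end runs."""
        defaults = dict(
            n_genes=72,
            n_network_genes=48,
            chromosome_length=120_000,
            timepoints=tuple(range(0, 20_001, 5_000)),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [asdict(p) for p in self.populations]
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = tuple(PopulationConfig(**p) for p in d["populations"])
        if "timepoints" in d:
            d["timepoints"] = tuple(int(t) for t in d["timepoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class SimulatedExperiment:
    network: PPINetwork
    genes: GeneTable
    disruptions: DisruptionTable
    fitness: pd.DataFrame
    config: SimulationConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the four TSVs consumed by the analysis pipeline."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": directory / "edges.tsv",
            "genes": directory / "genes.tsv",
            "disruptions": directory / "disruptions.tsv",
            "fitness": directory / "fitness.tsv",
        }
        write_edge_list(self.network, paths["edges"])
        write_gene_table(self.genes, paths["genes"])
        write_disruptions(self.disruptions, paths["disruptions"])
        self.fitness.to_csv(paths["fitness"], sep="\t", index=False)
        return paths


def _gene_label(i: int) -> str:
    return f"g{i:04d}"


def generate_network(config: SimulationConfig, seed: int | None = None) -> PPINetwork:
    """Ancestral interactome from the configured random-graph model.

    Default is duplication-divergence: repeatedly duplicate a random node,
    retain each parent edge with probability q, attach the duplicate to its
    parent with probability p; isolated duplicates are wired to the parent
    so every node interacts.  This yields a heavier-tailed degree
    distribution than a same-density Erdos-Renyi graph.
    """
    n = config.n_network_genes
    if n < 2:
        raise ValueError("need at least 2 network genes")
    rng = spawn_rng(config.seed if seed is None else seed, "network")
    labels = [_gene_label(i) for i in range(n)]
    model = config.network_model
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n, config.er_edge_p, seed=int(rng.integers(2**31)))
        edges = [(labels[a], labels[b]) for a, b in g.edges]
        return PPINetwork.from_edges(edges, extra_nodes=labels, name="ancestor")
    if model == "preferential_attachment":
        m = min(config.pa_m, n - 1)
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        edges = [(labels[a], labels[b]) for a, b in g.edges]
        return PPINetwork.from_edges(edges, extra_nodes=labels, name="ancestor")
    if model != "duplication_divergence":
        raise ValueError(f"unknown network model {config.network_model!r}")
    p, q = config.dd_attach_p, config.dd_retain_q
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError("duplication-divergence probabilities must be in [0, 1]")
    adj: list[set[int]] = [set() for _ in range(n)]
    adj[0].add(1)
    adj[1].add(0)
    for v in range(2, n):
        parent = int(rng.integers(v))
        for u in list(adj[parent]):
            if rng.random() < q:
                adj[v].add(u)
                adj[u].add(v)
        if rng.random() < p:
            adj[v].add(parent)
            adj[parent].add(v)
        if not adj[v]:
            adj[v].add(parent)
            adj[parent].add(v)
    edges = [
        (labels[a], labels[b]) for a in range(n) for b in adj[a] if a < b
    ]
    return PPINetwork.from_edges(edges, extra_nodes=labels, name="ancestor")


def generate_gene_table(
    config: SimulationConfig, network: PPINetwork, seed: int | None = None
) -> GeneTable:
    """Place genes on the circular chromosome and assign essentiality.

    Genomic order is shuffled so chromosome position carries no information
    about network structure.  Essential flags favor high-degree network
    genes through ``essential_enrichment`` (1.0 = independent of degree).
    """
    n = config.n_genes
    L = config.chromosome_length
    rng = spawn_rng(config.seed if seed is None else seed, "genes")
    labels = [_gene_label(i) for i in range(n)]
    lengths = rng.integers(300, 1_501, size=n)
    total = int(lengths.sum())
    if total > L:
        raise ValueError(
            f"total gene span {total} bp exceeds chromosome length {L} bp"
        )
    slack = L - total
    gaps = rng.multinomial(slack, np.full(n, 1.0 / n))
    order = rng.permutation(n)
    starts = np.zeros(n, dtype=int)
    cursor = 1
    for k, i in enumerate(order):
        starts[i] = cursor
        cursor += int(lengths[i]) + int(gaps[k])
    ends = (starts - 1 + lengths - 1) % L + 1
    strands = rng.choice(["+", "-"], size=n)

    degs = np.array([network.degree(g) for g in labels], dtype=float)
    n_essential = int(round(config.essential_fraction * n))
    essential = np.zeros(n, dtype=bool)
    if n_essential > 0:
        enrich = config.essential_enrichment
        if degs.max() > 0 and enrich != 1.0:
            weights = np.power(enrich, degs / degs.max())
        else:
            weights = np.ones(n)
        keys = rng.exponential(size=n) / weights
        chosen = np.argpartition(keys, n_essential - 1)[:n_essential]
        essential[chosen] = True

    df = pd.DataFrame(
        {
            "gene": labels,
            "start": starts,
            "end": ends,
            "strand": strands,
            "essential": essential,
        }
    )
    return GeneTable.from_records(df, chromosome_length=L)


def simulate_disruption_history(
    config: SimulationConfig,
    network: PPINetwork,
    genes: GeneTable,
    seed: int | None = None,
) -> DisruptionTable:
    """Accumulate disruptions along one lineage per population.

    Between consecutive timepoints the lineage gains Poisson-many events;
    each event picks a not-yet-disrupted gene with probability proportional
    to (degree + 1)^(-selection_gamma), rejects essential candidates with
    probability ``essential_protection`` (the event is lost: purifying
    selection removes it), and with probability ``deletion_block_rate``
    seeds a contiguous multi-gene deletion block.  Each timepoint yields
    ``clones_per_timepoint`` clones sharing the lineage set plus
    independent clone-private disruptions.
    """
    base_seed = config.seed if seed is None else seed
    gene_ids = genes.gene_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    degs = np.array([network.degree(g) for g in gene_ids], dtype=float)
    base_weights = np.power(degs + 1.0, -config.selection_gamma)
    essential = np.array([genes.is_essential(g) for g in gene_ids])
    genomic_order = list(genes.frame.sort_values("start").index)
    order_pos = {g: i for i, g in enumerate(genomic_order)}
    timepoints = sorted(config.timepoints)
    rows: list[dict] = []

    for pop in config.populations:
        rng = spawn_rng(base_seed, "disruptions", pop.label)
        lineage: dict[str, tuple[int, str, object]] = {}  # gene -> (gen, class, block)
        available = np.ones(len(gene_ids), dtype=bool)
        block_counter = 0

        def draw_gene(rng: np.random.Generator) -> str | None:
            idx = np.flatnonzero(available)
            if idx.size == 0:
                return None
            w = base_weights[idx]
            probs = w / w.sum()
            return gene_ids[int(rng.choice(idx, p=probs))]

        def accept(gene: str, rng: np.random.Generator) -> bool:
            if essential[gene_pos[gene]] and rng.random() < config.essential_protection:
                return False
            return True

        def add_single(gene: str, gen: int, rng: np.random.Generator, cls: str | None = None):
            if cls is None:
                cls = str(rng.choice(_SINGLE_CLASSES))
            lineage[gene] = (gen, cls, pd.NA)
            available[gene_pos[gene]] = False

        def add_block(seed_gene: str, gen: int, rng: np.random.Generator):
            nonlocal block_counter
            block_counter += 1
            block_id = f"{pop.label}_b{block_counter:03d}"
            size = 2 + int(rng.poisson(config.block_size_mean - 2.0))
            start = order_pos[seed_gene]
            members = [seed_gene]
            step = 1
            while len(members) < size and step < len(genomic_order):
                cand = genomic_order[(start + step) % len(genomic_order)]
                step += 1
                if not available[gene_pos[cand]]:
                    continue
                if not accept(cand, rng):
                    continue
                members.append(cand)
            for g in members:
                lineage[g] = (gen, "large_deletion", block_id)
                available[gene_pos[g]] = False

        prev_t = timepoints[0]
        for t in timepoints:
            dt = t - prev_t
            prev_t = t
            if dt > 0:
                lam = pop.rate_per_5k * pop.mutator * dt / 5_000.0
                for _ in range(int(rng.poisson(lam))):
                    gene = draw_gene(rng)
                    if gene is None:
                        break
                    if not accept(gene, rng):
                        continue
                    if rng.random() < config.deletion_block_rate:
                        add_block(gene, t, rng)
                    else:
                        add_single(gene, t, rng)
                if pop.mob_burst > 1.0:
                    lam_mob = lam * (pop.mob_burst - 1.0)
                    for _ in range(int(rng.poisson(lam_mob))):
                        gene = draw_gene(rng)
                        if gene is None:
                            break
                        if not accept(gene, rng):
                            continue
                        add_single(gene, t, rng, cls="mob_insertion")

            for c in range(1, config.clones_per_timepoint + 1):
                clone = f"{pop.label}:{t}:c{c}"
                crng = spawn_rng(base_seed, "clone", pop.label, t, c)
                private: dict[str, tuple[int, str, object]] = {}
                lam_priv = config.clone_private_rate * pop.mutator
                for _ in range(int(crng.poisson(lam_priv))):
                    idx = np.flatnonzero(available)
                    idx = idx[[gene_ids[i] not in private for i in idx]]
                    if idx.size == 0:
                        break
                    w = base_weights[idx]
                    gene = gene_ids[int(crng.choice(idx, p=w / w.sum()))]
                    if not accept(gene, crng):
                        continue
                    private[gene] = (t, str(crng.choice(_SINGLE_CLASSES)), pd.NA)
                for gene, (_, cls, block) in {**lineage, **private}.items():
                    rows.append(
                        {
                            "population": pop.label,
                            "generation": t,
                            "clone": clone,
                            "gene": gene,
                            "mutation_class": cls,
                            "deletion_block": block,
                        }
                    )

    frame = pd.DataFrame(rows, columns=list(DisruptionTable.COLUMNS))
    return DisruptionTable.from_frame(frame, genes=genes)


def simulate_fitness(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Saturating mean-fitness trajectories w(t) = (1 + c t)^b with noise."""
    if config.fitness_b < 0 or config.fitness_c < 0:
        raise ValueError("fitness parameters must be >= 0")
    rng = spawn_rng(config.seed if seed is None else seed, "fitness")
    rows = []
    for pop in config.populations:
        for t in sorted(config.timepoints):
            w = (1.0 + config.fitness_c * t) ** config.fitness_b
            if config.fitness_noise > 0:
                w *= float(np.exp(rng.normal(0.0, config.fitness_noise)))
            rows.append({"population": pop.label, "generation": t, "fitness": w})
    return pd.DataFrame(rows)


def generate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Compose network, gene table, disruption history and fitness."""
    network = generate_network(config)
    genes = generate_gene_table(config, network)
    disruptions = simulate_disruption_history(config, network, genes)
    fitness = simulate_fitness(config)
    return SimulatedExperiment(network, genes, disruptions, fitness, config)
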