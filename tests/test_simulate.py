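import time

import numpy as np
import pytest
from scipy import stats

from ppiresilience.simulate import (
    PopulationConfig,
    SimulationConfig,
    generate_experiment,
    generate_gene_table,
    generate_network,
    simulate_disruption_history,
    simulate_fitness,
)


class TestGenerateNetwork:
    def test_erdos_renyi_p_zero_is_edgeless(self):
        cfg = SimulationConfig.test_scale(network_model="erdos_renyi", er_edge_p=0.0)
        net = generate_network(cfg)
        assert net.n_edges == 0
        assert net.n_nodes == cfg.n_network_genes

    def test_erdos_renyi_p_one_is_complete(self):
        cfg = SimulationConfig.test_scale(
            network_model="erdos_renyi", er_edge_p=1.0, n_network_genes=12, n_genes=20
        )
        net = generate_network(cfg)
        assert net.n_edges == 12 * 11 // 2

    def test_duplication_divergence_heavy_tail(self):
        # top-5% degree share exceeds a same-density Erdos-Renyi graph's
        shares = {"duplication_divergence": [], "erdos_renyi": []}
        for seed in range(5):
            dd_cfg = SimulationConfig(
                n_genes=500, n_network_genes=500, chromosome_length=2_000_000, seed=seed
            )
            dd = generate_network(dd_cfg)
            dd_density = 2 * dd.n_edges / (500 * 499)
            er_cfg = SimulationConfig(
                n_genes=500, n_network_genes=500, chromosome_length=2_000_000,
                network_model="erdos_renyi", er_edge_p=dd_density, seed=seed,
            )
            er = generate_network(er_cfg)
            for label, net in (("duplication_divergence", dd), ("erdos_renyi", er)):
                degs = np.sort([net.degree(v) for v in net.nodes])[::-1]
                top = max(1, len(degs) // 20)
                shares[label].append(degs[:top].sum() / max(degs.sum(), 1))
        assert np.mean(shares["duplication_divergence"]) > np.mean(shares["erdos_renyi"])

    def test_no_isolated_nodes_in_dd_model(self):
        net = generate_network(SimulationConfig.test_scale())
        assert all(net.degree(v) >= 1 for v in net.nodes)

    def test_unknown_model(self):
        cfg = SimulationConfig.test_scale(network_model="small_world")
        with pytest.raises(ValueError, match="model"):
            generate_network(cfg)


class TestGenerateGeneTable:
    def test_essential_fraction_zero(self):
        cfg = SimulationConfig.test_scale(essential_fraction=0.0)
        net = generate_network(cfg)
        genes = generate_gene_table(cfg, net)
        assert len(genes.essential_genes) == 0

    def test_gene_span_fits_chromosome(self):
        cfg = SimulationConfig.test_scale()
        net = generate_network(cfg)
        genes = generate_gene_table(cfg, net)
        assert genes.frame["length"].sum() <= cfg.chromosome_length
        assert len(genes) == cfg.n_genes

    def test_overfull_chromosome_rejected(self):
        cfg = SimulationConfig.test_scale(chromosome_length=5_000)
        net = generate_network(cfg)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            generate_gene_table(cfg, net)

    def test_enrichment_one_is_degree_independent(self):
        # pooled over simulations: essentiality vs above-median degree
        table = np.zeros((2, 2), dtype=int)
        for seed in range(30):
            cfg = SimulationConfig.test_scale(seed=seed, essential_enrichment=1.0)
            net = generate_network(cfg)
            genes = generate_gene_table(cfg, net)
            degs = np.array([net.degree(g) for g in genes.gene_ids])
            ess = np.array([genes.is_essential(g) for g in genes.gene_ids])
            high = degs > np.median(degs)
            table[0, 0] += int((ess & high).sum())
            table[0, 1] += int((ess & ~high).sum())
            table[1, 0] += int((~ess & high).sum())
            table[1, 1] += int((~ess & ~high).sum())
        _, p = stats.fisher_exact(table)
        assert p > 0.001

    def test_enrichment_biases_toward_hubs(self):
        ess_deg, non_deg = [], []
        for seed in range(10):
            cfg = SimulationConfig.test_scale(seed=seed, essential_enrichment=50.0)
            net = generate_network(cfg)
            genes = generate_gene_table(cfg, net)
            for g in genes.gene_ids:
                (ess_deg if genes.is_essential(g) else non_deg).append(net.degree(g))
        assert np.mean(ess_deg) > np.mean(non_deg)


class TestDisruptionHistory:
    def test_rate_zero_empty_table(self):
        pops = tuple(
            PopulationConfig(f"p{i}", rate_per_5k=0.0) for i in range(1, 13)
        )
        cfg = SimulationConfig.test_scale(populations=pops, clone_private_rate=0.0)
        net = generate_network(cfg)
        genes = generate_gene_table(cfg, net)
        disr = simulate_disruption_history(cfg, net, genes)
        assert len(disr) == 0

    def test_protection_one_no_essential_disruptions(self):
        cfg = SimulationConfig.test_scale(essential_protection=1.0, essential_fraction=0.3)
        net = generate_network(cfg)
        genes = generate_gene_table(cfg, net)
        disr = simulate_disruption_history(cfg, net, genes)
        hit = set(disr.frame["gene"])
        assert not (hit & genes.essential_genes)

    def test_null_regime_degree_calibration(self):
        # gamma=0, protection=0: disrupted-gene degrees look like uniform
        # draws from the gene pool
        disrupted_degs, pool_degs = [], []
        for seed in range(25):
            cfg = SimulationConfig.test_scale(seed=seed)
            net = generate_network(cfg)
            genes = generate_gene_table(cfg, net)
            disr = simulate_disruption_history(cfg, net, genes)
            degs = {g: net.degree(g) for g in genes.gene_ids}
            disrupted_degs.extend(degs[g] for g in set(disr.frame["gene"]))
            pool_degs.extend(degs.values())
        res = stats.mannwhitneyu(disrupted_degs, pool_degs, alternative="two-sided")
        assert res.pvalue > 1e-4

    def test_selection_gamma_avoids_hubs(self):
        disrupted_degs, pool_degs = [], []
        for seed in range(10):
            cfg = SimulationConfig.test_scale(seed=seed, selection_gamma=3.0)
            net = generate_network(cfg)
            genes = generate_gene_table(cfg, net)
            disr = simulate_disruption_history(cfg, net, genes)
            degs = {g: net.degree(g) for g in genes.gene_ids}
            disrupted_degs.extend(degs[g] for g in set(disr.frame["gene"]))
            pool_degs.extend(degs.values())
        assert np.mean(disrupted_degs) < np.mean(pool_degs)

    def test_lineage_monotonicity(self):
        # the lineage stream is independent of the clone-private stream, so
        # a private-rate-0 run with the same seed exposes the pure lineage
        cfg_lineage = SimulationConfig.test_scale(seed=5, clone_private_rate=0.0)
        cfg_full = SimulationConfig.test_scale(seed=5)
        net = generate_network(cfg_full)
        genes = generate_gene_table(cfg_full, net)
        lineage_only = simulate_disruption_history(cfg_lineage, net, genes)
        full = simulate_disruption_history(cfg_full, net, genes)

        lineage_sets: dict[tuple[str, int], set] = {}
        for (pop, gen), grp in lineage_only.frame.groupby(["population", "generation"]):
            lineage_sets[(pop, gen)] = set(grp["gene"])
        # lineage itself is nested over generations
        for pop in {p for p, _ in lineage_sets}:
            gens = sorted(g for p, g in lineage_sets if p == pop)
            for earlier, later in zip(gens, gens[1:]):
                assert lineage_sets[(pop, earlier)] <= lineage_sets[(pop, later)]
        # every clone contains its lineage's disruptions up to its generation
        for (pop, gen, _clone), grp in full.frame.groupby(
            ["population", "generation", "clone"]
        ):
            assert lineage_sets.get((pop, gen), set()) <= set(grp["gene"])

    def test_deletion_blocks_are_genomically_contiguous_sets(self):
        cfg = SimulationConfig.test_scale(seed=3, deletion_block_rate=0.5)
        net = generate_network(cfg)
        genes = generate_gene_table(cfg, net)
        disr = simulate_disruption_history(cfg, net, genes)
        blocked = disr.frame[disr.frame["deletion_block"].notna()]
        assert len(blocked) > 0
        assert (blocked["mutation_class"] == "large_deletion").all()


class TestFitness:
    def test_b_zero_constant_one(self):
        cfg = SimulationConfig.test_scale(fitness_b=0.0, fitness_noise=0.0)
        fit = simulate_fitness(cfg)
        assert (fit["fitness"] == 1.0).all()

    def test_t_zero_is_one_without_noise(self):
        cfg = SimulationConfig.test_scale(fitness_noise=0.0)
        fit = simulate_fitness(cfg)
        assert (fit.loc[fit["generation"] == 0, "fitness"] == 1.0).all()

    def test_closed_form_endpoint(self):
        cfg = SimulationConfig.test_scale(
            fitness_b=0.3, fitness_c=0.001, fitness_noise=0.0,
            timepoints=(0, 50_000),
        )
        fit = simulate_fitness(cfg)
        w_final = fit.loc[fit["generation"] == 50_000, "fitness"].iloc[0]
        assert w_final == pytest.approx(51.0**0.3)
        assert w_final == pytest.approx(3.25, abs=0.01)


class TestGenerateExperiment:
    def test_smoke_under_ten_seconds(self):
        t0 = time.time()
        cfg = SimulationConfig(seed=1)  # production-default 200-gene network
        exp = generate_experiment(cfg)
        assert time.time() - t0 < 10
        assert exp.network.n_nodes == cfg.n_network_genes
        assert len(exp.genes) == cfg.n_genes
        assert len(exp.fitness) == 12 * len(cfg.timepoints)

    def test_every_disrupted_gene_in_gene_table(self):
        exp = generate_experiment(SimulationConfig.test_scale(seed=2))
        assert set(exp.disruptions.frame["gene"]) <= set(exp.genes.gene_ids)

    def test_round_trip_through_tsv(self, tmp_path):
        from ppiresilience.core import read_disruptions, read_edge_list, read_gene_table

        exp = generate_experiment(SimulationConfig.test_scale(seed=4))
        paths = exp.write(tmp_path)
        net = read_edge_list(paths["edges"])
        genes = read_gene_table(paths["genes"], chromosome_length=exp.config.chromosome_length)
        disr = read_disruptions(paths["disruptions"], genes)
        assert net.edges == exp.network.edges
        assert len(genes) == len(exp.genes)
        assert len(disr) == len(exp.disruptions)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = SimulationConfig.test_scale(seed=9, selection_gamma=1.5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg

    def test_determinism(self):
        a = generate_experiment(SimulationConfig.test_scale(seed=6))
        b = generate_experiment(SimulationConfig.test_scale(seed=6))
        assert a.network.edges == b.network.edges
        assert a.disruptions.frame.equals(b.disruptions.frame)
        assert a.fitness.equals(b.fitness)
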