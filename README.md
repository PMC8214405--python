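# ppiresilience

Analysis pipeline for studying how protein-interactome resilience evolves
under long-term accumulation of loss-of-function mutations. Given an
ancestral protein–protein interaction (PPI) network, a gene table on a
circular chromosome, and per-clone gene-disruption tables, it:

- prunes the ancestral network by each clone's disrupted genes
  (`ppiresilience.core`),
- measures network resilience as one minus the mean normalized Shannon
  entropy of component sizes under random node failure, averaged over a
  failure-rate grid and Monte-Carlo removal replicates
  (`ppiresilience.resilience`),
- builds two randomized counterpart ensembles per clone — uniform sampling
  over all genes, and sampling restricted to ever-disrupted genes weighted
  by cross-population disruption frequency (`ppiresilience.nulls`),
- compares per-population evolved vs randomized resilience slopes with an
  exact paired Wilcoxon signed-rank test, plus rank-sum / binomial /
  Fisher / Pearson tests for the secondary analyses
  (`ppiresilience.evostats`),
- runs single-gene disruption scans and deletion diagnostics (ancestral
  degree by mutation class, circular genomic distance of removed
  interactions) (`ppiresilience.scans`),
- generates complete synthetic experiments — scale-free-like interactome,
  12 populations × 11 timepoints × 2 clones, mutator and transposon-burst
  populations, a tunable purifying-selection knob, saturating fitness —
  so the whole pipeline is testable offline (`ppiresilience.simulate`).

All inputs and outputs are plain UTF-8 TSV; simulation configs are YAML.

## CLI

```sh
# generate a synthetic experiment (reduced test scale by default)
ppi-resilience simulate --seed 1 --outdir sim/

# full analysis: evolved + null resilience, slopes, paired tests,
# fitness correlation, deletion/essentiality diagnostics
ppi-resilience analyze \
    --edges sim/edges.tsv --genes sim/genes.tsv \
    --disruptions sim/disruptions.tsv --fitness sim/fitness.tsv \
    -K 10 -M 10 -R 20 --seed 1 --outdir out/

# stage-wise commands
ppi-resilience resilience --edges ... --genes ... --disruptions ... --out res.tsv
ppi-resilience nulls --scheme weighted_disrupted ... --out nulls.tsv
ppi-resilience scan ... --out scan.tsv
ppi-resilience report --outdir out/
```

Exit codes: 0 success, 2 validation error, 3 computation error. Every
`analyze` run writes a `manifest.json` recording the failure grid, seeds,
input digests and outputs.

Defaults worth knowing: the failure grid uses rates k/K for k = 0..K−1
(f = 1 excluded), removing ⌊f·N⌋ nodes uniformly without replacement;
production defaults are K = 100, M = 50, while tests use reduced grids.
Null-set sizes count all disrupted genes of the matched clone (including
genes outside the interactome); header presence in TSVs is a flag, never
guessed. Synthetic disruption rates are order-of-magnitude placeholders,
not estimates.

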