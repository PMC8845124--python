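# phylodissect

Dissection of phylogenetic signal in multilocus amino-acid data sets.

When two topology hypotheses compete for a deep node — say, a focal clade
that is either monophyletic (T2) or has an "outpost" lineage nested inside
it (T1) — raw support values rarely settle the question: long-branch
attraction, saturation, and short noisy loci can manufacture apparent
signal for either side. `phylodissect` implements the standard
signal-dissection toolkit for this situation:

- **Matrix construction**: clade-decisiveness filtering (keep only loci
  sampling ≥ 1 taxon of every required clade), concatenation with
  partition ranges, occupancy bookkeeping.
- **Saturation subsampling**: per-locus regression of uncorrected
  p-distance on patristic distance; slowly evolving loci selected by
  slope ≥ 0.4 and r² ≥ 0.95.
- **Likelihood engine**: Felsenstein pruning under reversible amino-acid
  models (LG, WAG, Poisson; +F frequencies; discrete-Γ rates), with
  pattern compression, per-node rescaling, and per-branch Brent
  optimisation of branch lengths on a fixed topology.
- **Signal scores**: gene-wise ΔGLS = lnL(locus | T1) − lnL(locus | T2)
  and its per-site analogue ΔSLS (which sums exactly to ΔGLS at fixed
  branch lengths), support-class proportions, and per-class comparison of
  the covariates linked to systematic error (length, informative sites,
  missing data, rate, saturation).
- **Diagnostics**: per-column Shannon entropy, entropy/gap trimming, SR4
  four-state recoding, and gene/site concordance factors (gCF/sCF) for
  the branches of each hypothesis.
- **Synthetic data**: a generator producing species trees with designated
  fast-evolving lineages, rate- and length-heterogeneous loci, an optional
  minority "noise" class simulated on the alternative topology, and
  realistic patchy occupancy — so the whole pipeline is testable
  end-to-end with no external data.

## Worked example

Simulate a 12-taxon study in which 75% of loci evolve on T1 under LG+Γ and
a 25% minority of short, ten-fold-faster loci evolve on T2 (the "noise"
class), then run every stage:

```python
from phylodissect.pipeline import RunConfig, run_pipeline

config = RunConfig.from_mapping({
    "output_dir": "demo_out",
    "seed": 1,
    "simulation": {
        "n_taxa": 12, "n_loci": 30, "seed": 1,
        "locus_length_range": [150, 400], "dropout_prob": 0.15,
        "noise_fraction": 0.25, "noise_rate_multiplier": 10.0,
        "noise_length_range": [60, 120],
    },
    "n_quartets": 50,
})
results = run_pipeline(config)
```

The run writes `signal_table.csv`, `saturation.csv`, `site_scores.csv`,
`property_comparison.csv`, concordance tables, plots, a summary and a
hashed manifest into `demo_out/`, and returns the headline numbers. With
the configuration above it prints (in `results.json`):

```
n_loci_input 30 -> n_loci_decisive 29 -> n_loci_slow 1
gene_support:  T1 72.4%   T2 27.6%
median_site_entropy_by_class:  T1 0.898   T2 1.168
```

Reading: 29 of 30 loci sample every clade; after the mixed noise class is
injected, only a minority of genes (27.6%) backs the T2 topology, and those
genes are shorter (median length ratio ≈ 0.33), carry fewer
parsimony-informative sites (ratio ≈ 0.57), and their supporting sites show
higher Shannon entropy (1.168 vs 0.898 nats) — the classic signature of
support arising from noise rather than history. The same numbers are in
`demo_out/summary.txt` and the per-locus detail in
`demo_out/signal_table.csv`.

The command line mirrors the stages:

```bash
phylodissect simulate --n-taxa 12 --n-loci 30 --seed 1 -o study/
phylodissect filter study/loci study/clade_map.tsv -o study/decisive
phylodissect saturation study/loci study/gene_trees -o saturation.csv
phylodissect all config.yaml        # full pipeline from a YAML config
```

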