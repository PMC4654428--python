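# rdsoil

Statistics pipeline for soil-disinfection biotests. It reimplements, as a
tested and reusable package, the analysis path of a greenhouse
replant-disease experiment: community fingerprints, 16S OTU tables,
diversity, ordination, per-taxon responder screening, and plant-growth
statistics — with synthetic-data generators standing in for the wet-lab
inputs so that every stage can be exercised offline.

## Modules

| Module | What it does |
| --- | --- |
| `rdsoil.synth` | Simulators: gel-style lane intensity profiles, Dirichlet-multinomial OTU tables with planted responder effects, growth tables, qPCR copy-number tables. Pure functions of `(params, seed)`. |
| `rdsoil.fingerprint` | Pairwise Pearson similarity of lane profiles, UPGMA dendrograms (Newick), and the permutation *d*-test (100 × mean within-group minus mean between-group similarity; exhaustive enumeration up to a configurable cap, Monte-Carlo beyond). |
| `rdsoil.community` | OTU-table handling: taxonomic aggregation, relative abundance, the `log10(n/N·100 + 1)` transform, dominance filtering (≥1 % mean relative abundance), analytic hypergeometric rarefaction, unbiased inverse-Simpson diversity. |
| `rdsoil.ordination` | Bray–Curtis distances, principal coordinate analysis, one-way and two-way (within-block) ANOSIM permutation tests. |
| `rdsoil.screen` | Per-taxon treatment screen: one-way ANOVA, Tukey HSD with compact letter display, Dunnett many-to-one tests, responder direction vs. control; diversity and qPCR group comparisons. |
| `rdsoil.biotest` | Growth-table statistics: group mean ± SD summaries, percent/fold increase vs. control, root-to-shoot ratio, per-week Dunnett time-course flags, Levene variance check. |
| `rdsoil.pipeline` / `rdsoil.cli` | YAML-configured end-to-end driver with a deterministic report bundle and run manifest. |

## CLI

```sh
# emit a demo synthetic dataset (lanes.csv, otu.tsv, taxonomy.tsv, metadata.tsv, growth.csv)
rdsoil synth --out demo --seed 1

# permutation d-test between two groups of lanes
rdsoil fingerprint --profiles demo/lanes.csv --compare KleCon:KleH50 --seed 1

# Bray–Curtis PCoA + ANOSIM on the genus-level table (dominant phyla only)
rdsoil ordinate --table demo/otu.tsv --tax demo/taxonomy.tsv \
    --meta demo/metadata.tsv --out demo_ord --seed 1

# growth-table report with Tukey letters and derived columns
rdsoil biotest --growth demo/growth.csv --control Con

# full pipeline from a YAML config
rdsoil run --config config.yaml --out results/
```

A minimal `config.yaml` looks like:

```yaml
seed: 1
alpha: 0.05
stages: {fingerprint: true, diversity: true, ordination: true, screen: true, biotest: true}
synth:
  fingerprints: {n_groups: 4, group_labels: [KleCon, KleH50, AlvCon, AlvH50]}
  otu: {groups: ["Kle:Con", "Kle:H50", "Alv:Con", "Alv:H50"], n_otus: 50}
  growth:
    group_means: {"Kle:Con": [30, 4.3, 3.1, 2.7], "Kle:H50": [40, 9.2, 4.5, 3.0]}
    group_sds:   {"Kle:Con": [3, 1, 0.4, 0.5],    "Kle:H50": [3, 1, 0.4, 0.5]}
```

Each data stream comes either from `synth:` parameters or from explicit
`inputs:` file paths (lane CSV, OTU/taxonomy/metadata TSV, growth CSV) —
never both.

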