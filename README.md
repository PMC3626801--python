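# coexnet

Signed weighted gene coexpression network analysis for transcriptome studies:
module detection via topological overlap and adaptive dendrogram cutting,
module eigengene statistics against clinical traits and groups, EASE-style
gene-set enrichment, and a cross-disease comparison of impairment-correlated
transcription. A first-class synthetic-data module plants known coexpression
and trait structure so every stage can be validated against ground truth.

## What it does

* **`coexnet.synthetic`** — latent-factor generator for expression studies:
  planted modules with tunable within-module correlation, eigengenes
  correlated with an impairment score (GCR, 1–9, higher = worse; or MMSE,
  0–30, lower = worse), per-group mean shifts, multiple probes per gene,
  Bernoulli presence calls, and paired two-disease designs sharing a planted
  impairment-gene set. Fully determined by a single seed.
* **`coexnet.preprocess`** — inter-array-correlation outlier detection,
  quantile normalization, absent-call filtering (drop rows absent in >90% of
  samples, or keep rows detected in ≥6 samples for network input), and
  max-mean probe-to-gene collapsing.
* **`coexnet.network`** — signed adjacency `((cor + 1)/2)^beta` (default
  beta = 12, so r = −1 → 0 and r = +1 → 1), topological overlap, average
  linkage on 1 − TO with adaptive branch cutting (minimum module size 30 by
  default; unassigned genes are "grey"), and hypergeometric label matching
  between networks.
* **`coexnet.module_stats`** — module eigengenes (first principal component
  of the z-scored module submatrix, sign-oriented), kME membership, scaled
  intramodular connectivity (kIN / max kIN), eigengene–trait Pearson
  correlations, ANOVA + Kruskal–Wallis group tests, and a permutation
  composite of density/connectivity module preservation.
* **`coexnet.enrichment`** — per-gene trait correlation tables, top-gene
  tables (|R| ≥ 0.75), and EASE-score enrichment: a jackknifed one-tailed
  Fisher exact probability (one gene removed from the category's list hits)
  with source-specific population universes and Bonferroni adjustment, plus
  plain hypergeometric marker-set enrichment for modules.
* **`coexnet.cross_disease`** — common-gene alignment between two studies,
  impairment correlation vectors (GCR directly, MMSE sign-flipped),
  quadrant classification of impairment genes (all correlations strictly
  beyond ±0.25), enrichment of the common up/down sets, hypergeometric
  flags for modules enriched in the second disease's impairment genes, and
  the common-hub table (scaled kIN > 0.70 in both diseases).
* **`coexnet.pipeline` / CLI** — orchestrates
  preprocess → network → stats → enrich → crossdisease from a plain-text
  config with deterministic outputs and a manifest.

## CLI

```bash
# generate synthetic fixtures from a YAML design
coexnet simulate --design design.yaml --out fixtures/

# run the full pipeline from a config file
coexnet run-all --config pipeline.ini --seed 1

# or a prefix of the stages
coexnet network --config pipeline.ini
```

A design file looks like:

```yaml
seed: 1
noise_sd: 0.5
n_background_genes: 200
samples_per_group: {A: 6, B: 4, C: 7, D: 4}
absent_fraction: 0.05
probes_per_gene: 2
modules:
  - {module_id: M1, size: 100, factor_loading: 0.9, trait_effect: 0.5}
  - {module_id: M2, size: 60, factor_loading: 0.9}
```

A pipeline config is INI-style with one section per stage; unknown keys are
rejected before any computation:

```ini
[inputs]
expression = fixtures/expression.tsv
phenotypes = fixtures/phenotypes.csv
presence = fixtures/presence.tsv
probe_map = fixtures/probe_map.tsv
gene_sets = annotations.gmt

[network]
beta = 12
min_module_size = 30

[pipeline]
seed = 1
out_dir = out/
```

File formats are plain text: TSV expression/presence matrices (first column
gene/probe id, header row of sample ids), CSV phenotypes
(`sample_id,group,GCR,CPE,MMSE`, empty cell = missing), two-column TSV probe
maps, and GMT gene-set collections.

## Notes and caveats

* Module counts are sensitive to the cut parameters (`min_module_size`,
  `cut_height`, `deep_split`); this is inherent to dendrogram-based module
  detection.
* The outlier rule is a deterministic mean-IAC threshold (flag arrays below
  grand mean − 2 SD); the single-linkage dendrogram order is emitted for
  manual inspection. RNA-quality metadata are out of scope.
* The preservation statistic is a reduced two-statistic permutation
  composite (density + connectivity), not the full preservation-statistic
  suite.
* Array-platform preprocessing (MAS5 and friends) is out of scope: the
  pipeline starts from a probe- or gene-level matrix with optional presence
  calls.
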