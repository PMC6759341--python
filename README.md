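# myconest

Community analysis for paired intact/disturbed OTU count tables along an
environmental gradient: depth standardization, diversity, Bray-Curtis
dissimilarity, Mantel and PERMANOVA permutation tests, NODF nestedness with a
column-total-fixed Monte-Carlo null, and per-OTU disturbance-tolerance
indices (responsiveness/robustness/occurrence). A synthetic paired-design
generator with planted nestedness and tolerance signals makes the whole
chain testable without field data.

Matrix orientation is fixed everywhere: rows are OTUs, columns are samples.

## Library overview

| module | contents |
|---|---|
| `myconest.data_model` | `CountTable`, `SampleMetadata`, `PairedDesign`; TSV/BIOM-JSON readers and writers; `standardize_depth` (exact rarefaction without replacement), `combine_paired`, `presence_absence` |
| `myconest.diversity` | richness, Shannon-Wiener (nats by default), `bray_curtis`, `dissimilarity_matrix`, `rarefaction_curve` (by reads or by samples) |
| `myconest.perm_stats` | `pearson_correlation`, `mantel_test` (random or exact enumeration), `permanova_oneway`, `anova_tukey` with compact letter display, `fit_log_model` |
| `myconest.nestedness` | `pack_matrix`, `nodf` (columns/rows/total), `null_column_fixed`, `nodf_significance` (z-score and two-sided Monte-Carlo p) |
| `myconest.disturbance` | cell-wise log10(x+1) transform, `disturbance_profiles`, `robustness_occurrence_fit` |
| `myconest.synthetic` | `SimulationParams`, `simulate_dataset`, `simulate_null_dataset` |
| `myconest.pipeline` | `AnalysisConfig`, `run_full_analysis` — the eight-stage end-to-end chain |

Permutation p-values use the add-one convention `(count + 1)/(n_perm + 1)`.
The NODF z-score is `(observed − null mean)/null SD`; positive significant
values indicate nestedness, negative anti-nestedness.

## CLI

```sh
# simulate a paired dataset (counts.tsv, metadata.tsv, truth tables)
myconest simulate --seed 7 --out data/

# individual stages
myconest standardize --counts data/counts.tsv --depth 10000 --seed 1 --out std.tsv
myconest diversity   --counts data/counts.tsv --metadata data/metadata.tsv --out div.tsv
myconest mantel      --counts data/counts.tsv --metadata data/metadata.tsv --factor elevation --seed 1
myconest permanova   --counts data/counts.tsv --metadata data/metadata.tsv --group habitat --seed 1
myconest nestedness  --counts data/counts.tsv --metadata data/metadata.tsv --seed 1 --packed-out packed.tsv
myconest disturbance --counts data/counts.tsv --metadata data/metadata.tsv --seed 1 --out profiles.tsv

# everything at once from a YAML config
myconest run-all --config config.yml
```

A minimal `config.yml`:

```yaml
counts: data/counts.tsv
metadata: data/metadata.tsv
outdir: results/
depth: 10000
n_perm: 9999
n_null: 1000
seed: 1
```

`run-all` writes one artifact per stage (standardized table, year/habitat
PERMANOVA, diversity + factor correlations, Tukey letters, Mantel sweep,
packed matrix + NODF, disturbance profiles + logarithmic fit) plus
`run_config.json` with every seed and setting needed to reproduce the run.

Usage errors exit 2; data errors exit 1 with the cause on stderr.

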