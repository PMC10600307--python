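# Run configuration

`phenosel report --config cfg.yml` (or `phenosel.io.run_pipeline`)
drives the full pipeline from a single YAML file. All keys map to
fields of `phenosel.io.RunConfig`; unknown keys are rejected, and the
seed is mandatory — there is no wall-clock fallback.

| key | type | default | meaning |
|---|---|---|---|
| `out_dir` | path | required | output directory (created) |
| `seed` | int | required | master seed for every random stage |
| `simulate` | mapping | null | `scenario_default` keyword arguments; when set, inputs are simulated |
| `plot_csv` | path | null | plot table (required unless simulating) |
| `spectra_csv` | path | null | plot-level spectra table |
| `marker_csv` | path | null | genotype x marker table |
| `chrom_map_csv` | path | null | marker -> chromosome map |
| `pretreatment` | one of `means`, `detrend`, `sg1`, `sg2` | `sg1` | spectral filter applied to adjusted genotype spectra |
| `sg_window` | odd int | 37 | Savitzky-Golay window (points) |
| `maf_threshold` | float | 0.05 | minor-allele-frequency cutoff |
| `impute_method` | `column_mode`, `column_mean_rounded`, `knn` | `column_mode` | marker imputation |
| `cv_sizes` | list of int | [100, 200, 300, 400] | sampled population sizes |
| `cv_reps` | int | 20 | repetitions per size |
| `cv_folds` | int | 5 | folds |
| `traits` | list | ["GY"] | primary traits to predict |
| `secondary_trait` | label | "PC" | bias-reference trait |

Validated example (synthetic inputs):

```yaml
out_dir: runs/demo
seed: 42
simulate:
  n_geno: 150
  n_markers: 250
  grid_points: 80
pretreatment: sg1
sg_window: 17
cv_sizes: [60, 100, 130]
cv_reps: 10
traits: [GY]
secondary_trait: PC
```

Outputs written to `out_dir`: per-location BLUE tables
(`blues_<loc>.csv`), `repeatability.csv`, `heritability.csv`, `G.csv`,
`H_<filter>_<loc>.csv`, tidy `cv_records.csv` + `cv_summary.csv`,
`indices.csv`, and `manifest.json` recording seeds, stage list and
input hashes — enough to reproduce any stage in isolation.
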