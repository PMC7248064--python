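# frogdensity

Estimation of **minimum adult frog density** and range-wide minimum
population size from large-scale audial (calling-male) surveys, together
with survey-quality metrics, a visual-count correction, and a synthetic
survey simulator for validation.

The core estimator extrapolates per-site best counts of simultaneously
calling males to all plot habitat within four strata — small (< 0.5 ha),
medium (0.5–10 ha) and large (> 10 ha) lentic waterbodies, plus ditches —
and divides by the product of three behavioural proportions (`ma`, the
fraction of present males calling at peak; `mp`, the fraction of the male
population present in waterbodies at peak; `ms`, the population sex ratio)
to obtain a deliberate lower bound on adult density. Medians of this
density, scaled by range area and plot-presence fractions, give
conservative national population estimates.

## Modules

| module | contents |
| --- | --- |
| `core_data` | record types, CSV I/O and validation, waterbody classification, relative date/daytime transforms, shipped taxon parameters |
| `survey_metrics` | best-year selection, WDP / IYF / CMPS, plot occupancy summaries |
| `density` | stratum tallies, calling-male density, minimum adult density, stratum contributions |
| `visual_correction` | detection-probability inflation of visual counts, virtual calling males, corrected density and covered fraction |
| `extrapolation` | range-wide minimum population, Monte-Carlo / delta-method uncertainty |
| `synthetic_data` | binomial-thinning survey simulator with known truth, recovery experiments |

## Input files

A dataset directory holds UTF-8, comma-delimited CSVs with header rows:

- `waterbodies.csv` — `waterbody_id, plot_id, category, area_ha, perimeter_m,
  length_m, surveyed, sampled_length_m`
- `surveys.csv` — `survey_id, plot_id, year, calendar_date (ISO),
  mid_time_hours, sunset_time_hours, earliest_season_date, …`
- `call_counts.csv` — `survey_id, waterbody_id, taxon, count,
  chorus_averaged, calling_index`
- `visual_records.csv` (optional) — `waterbody_id, taxon, year, adults_seen,
  sex_known, egg_masses, visibility_class, tadpoles_seen, metamorphs_seen`
- `plots.csv` (optional) — `plot_id, area_km2` (default 25 km²)

Taxon parameters (with defaults for the seven Latvian taxa, including
hearing distances and range areas) can be overridden with a YAML mapping
passed via `--params`.

## CLI

```bash
frogdensity simulate --config examples/simulation.yaml --out-dir data/
frogdensity metrics data/ --out metrics.csv
frogdensity density data/ --out density.csv          # + density_summary.csv
frogdensity correct-visual data/ --out corrections.csv
frogdensity extrapolate --density-summary density_summary.csv \
    --method mc --n-draws 100000 --seed 1 --out state.csv
```

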