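# weedrot

Density-structured population dynamics and bioeconomics of crop-rotation
strategies for managing a herbicide-resistant arable grass weed.

The package tracks a field's weed population as a distribution over five
ordinal density states (absent / low / medium / high / very high),
estimates year-on-year state transitions with a hierarchical
cumulative-logit model driven by management covariates, and evaluates
rotation strategies economically (itemised gross margins with a
density-responsive winter-wheat yield). Scenarios are compared through
opportunity costs (gross-profit difference) and productivity costs
(wheat-yield difference), including 18-year "switch now or later"
sequences from a worst-case starting density and national scale-up over
county cereal areas.

## Modules

| module | role |
| --- | --- |
| `weedrot.synthetic_data` | generates surveys, resistance assays, management histories, transition datasets from a known model, and packaged price/area tables — everything the pipeline needs, reproducibly from a seed |
| `weedrot.classification` | maps quadrat grids and assay mortalities to density categories, the low/high resistance dichotomy (72% mortality cut-off) and the LD-LR / LD-HR / HD-HR classes |
| `weedrot.strategies` | BAU (ww-ww-osr), continuous-winter-wheat and mitigation rotations; validation of the qualitative MIT design constraints; BBB/BBM/BMM/MMM switching sequences |
| `weedrot.density_model` | proportional-odds cumulative-logit transition model: penalised-likelihood fitting, multiple imputation for unobserved crop transitions, Markov forward simulation |
| `weedrot.econmod` | prices, base yields, yield penalties; per-year cost breakdowns, gross profit and density-weighted wheat yield with lower/central/upper sensitivity bounds |
| `weedrot.comparison` | opportunity/productivity costs, cumulative 18-year series, county scale-up, scenario summary reports |
| `weedrot.pipeline` | configuration, seed fan-out, stage wiring, run manifests |

The numeric tables under `src/weedrot/data/` (prices, base yields, yield
penalties, county areas, the 27 mitigation rotations) are editable
stand-in fixtures; replacing the CSVs swaps in real values without code
changes.

## Command line

```bash
weedrot run --seed 1 --out out/            # full pipeline on synthetic data
weedrot simulate-data --seed 1 --out out/  # surveys, assays, histories
weedrot classify out/surveys.csv out/assays.csv
weedrot fit out/transitions.csv --seed 1 --out model.json
weedrot validate path/to/strategies.csv
weedrot worst-case --seed 1 --out out/
weedrot reproduce-worked-examples
```

`weedrot run` writes tidy CSVs for every stage plus `manifest.json`
recording per-stage seeds, timings and output checksums; re-running the
same config reproduces identical outputs.

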