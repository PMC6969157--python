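# fishp

Global fishery phosphorus (P) budget accounting. The package quantifies the
two opposing anthropogenic P fluxes driven by fish production and their net
balance through time:

- **P-harvest** — P removed from aquatic systems in harvested biomass:
  `sum_i W_i * R_i` over species, with live-weight production `W_i` (wild
  capture optionally rescaled by country-level catch-reconstruction factors)
  and wet-basis whole-body P concentration `R_i` resolved through a
  taxonomic fallback chain (species → order → major group → database).
- **P-input** — P added through aquaculture feed and fertilizer, inferred as
  `sum_j P_harvest,j / PUE_j` over six environment × taxon groups, with
  group phosphorus-use efficiency (PUE) taken as the median of an empirical
  culture-system pool.
- **P-net** — harvest minus input, with trend statistics (peak year, first
  persistently negative year) and country/continent aggregation.

Uncertainty is propagated by Monte Carlo (default 1000 replicates):
per-replicate draws of species concentrations, uniform biomass perturbation,
and per-group PUE from the empirical pools, summarized as means with
interquartile ranges. Forward scenarios project the budget to a horizon year
and solve for the PUE at which the fishery becomes P-neutral; weighted
efficiency calculators (arithmetic and harmonic) translate retention
efficiencies from feeding experiments into system-level targets.

A synthetic-data module generates all five input tables (production,
concentrations, PUE, retention efficiencies, scaling factors) with known
ground truth, so the entire pipeline is testable offline, including
parameter-recovery experiments.

## CLI

The four subcommands form a reproducible pipeline; every run writes a JSON
manifest with input hashes, config, and seed.

```sh
# 1. generate synthetic inputs (or supply your own CSVs in the same schemas)
fishp synth --seed 1 --out-dir synth_out

# 2. compute the budget: point estimate + Monte Carlo IQR bands
fishp budget --production synth_out/production.csv \
             --concentration synth_out/concentration.csv \
             --pue synth_out/pue.csv --scaling synth_out/scaling.csv \
             --n-rep 1000 --biomass-level 0.5 --seed 1 --out-dir budget_out

# 3. aggregate and extract trend statistics
fishp trends --budget budget_out/budget_records.csv \
             --region-map synth_out/region.csv --out-dir trends_out

# 4. project to 2050 and solve the neutral-PUE target
fishp scenario --history budget_out/history.csv --out scenario.json
```

Input schemas (CSV headers) are defined in `fishp.data_io`: production
(`year,country,species,order,group,environment,source,weight[,unit]`),
concentration (`species,order,group,value,basis,moisture,origin`), pue
(`group6,value,system,country`), pre (`group,value`), scaling
(`country,year,factor`), region (`country,region,year_start,year_end`).
Tonnage is converted to Tg at the boundary; dry-basis concentrations are
converted to wet basis using record moisture or the database mean; brackish
environments fold into marine.

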