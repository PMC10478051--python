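# foodenv

Longitudinal food-environment equity analysis on establishment registries:

- **`foodenv.synth`** — synthetic establishment registries, tract-year
  attribute panels (race/ethnicity %, controls, SVI scores) and lattice
  tract geometries with known ground truth (log-linear Poisson outlet
  intensities, tract/year effects, optional planted healthy-outlet cluster).
- **`foodenv.taxonomy`** — NAICS-based classification into seven food-retail
  categories and three health tiers, including the small-grocery →
  convenience reclassification (fewer than five employees) and the
  dollar-store name filter.
- **`foodenv.indices`** — balanced tract-year panels of the modified Retail
  Food Environment Index (mRFEI), the Herfindahl-Hirschman index (HHI) of
  sales concentration with competitive/moderate/high bands, and the
  two-criterion (low-income + low-access) food-desert classifier.
- **`foodenv.spatial`** — queen-contiguity / distance-band spatial weights,
  Getis-Ord Gi* hot-spot z-scores with signed 90/95/99% confidence bins,
  and cross-year cluster-transition summaries.
- **`foodenv.ppml`** — Poisson pseudo-maximum-likelihood with tract and
  year fixed effects absorbed by weighted alternating projections,
  singleton/separation dropping, tract-clustered sandwich standard errors,
  and the full model grid ({mRFEI, HHI} × {race, Hispanic} ×
  {all, metro, non-metro} plus SVI variants).
- **`foodenv.pipeline` / `foodenv.cli`** — end-to-end orchestration with a
  reproducibility manifest (per-stage SHA-256 hashes).

## CLI

```sh
foodenv simulate  --outdir data --seed 1
foodenv classify  --establishments data/establishments.csv --out data/classified.csv
foodenv indices   --establishments data/classified.csv --years 2000:2019 --out data/panel.csv
foodenv hotspots  --indices data/panel.csv --geoms data/tracts.geojson \
                  --value mrfei --years 2000,2010,2019 --scheme queen --out data/hs
foodenv regress   --panel data/panel.csv --attributes data/tract_attributes.csv \
                  --outcome mrfei --model race --subset all --out data/reg
foodenv run-all   --config config.yaml        # full chain + manifest.json
foodenv make-fixtures --outdir tests_data     # 5x5-lattice mini bundle
```

`--config` accepts a YAML `RunConfig` (synthesis block, dollar-store tier
override, weights scheme, hot-spot years, seed). User-supplied data can
replace the synthesis stage: point `establishments` / `attributes` /
`geoms` at CSV/GeoJSON files with the documented schemas (see the column
lists in `foodenv.synth.write_bundle` outputs).

## Notes

- All interchange formats are plain text: CSV, GeoJSON (RFC 7946), JSON,
  YAML.
- With a fixed seed every stage is byte-reproducible; `run-all` writes a
  manifest with per-output SHA-256 hashes to verify this.
- Dollar stores carry no tier in the three-tier scheme's source; they
  default to the unhealthy tier and can be overridden (`--dollar-tier`,
  `dollar_tier` in config). The mRFEI denominator excludes
  intermediate-tier outlets (full-service restaurants).
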