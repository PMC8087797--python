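# fluvialfire

Analysis pipeline for wildfire impacts on stream networks. It quantifies the
stream + river length falling inside severity-filtered burn footprints
(per fire, per year, per ecoregion), robust trends and regressions on those
totals, and the downstream longitudinal extent of water-quality disturbance
inferred from multi-station dissolved-oxygen (DO) sags — via a biexponential
distance-decay fit and a Horton stream-length (geometric-series) model.
A seeded synthetic-data generator provides Hortonian stream networks, burn
scars with severity patches, ecoregion partitions and sonde DO series, so the
whole pipeline runs and is tested without any external downloads.

All geometry is planar Cartesian in kilometres. Real inputs (pre-projected
to an equal-length-preserving CRS) can be supplied in the same GeoJSON/CSV
schemas the generator writes.

## Layout

| module | purpose |
| --- | --- |
| `fluvialfire.synthetic_data` | seeded generators: Horton network, burn scars, ecoregions, DO series |
| `fluvialfire.sl_ba` | severity filter, minimum-area filter, network clipping, ecoregion attribution, annual aggregation |
| `fluvialfire.trend_stats` | Theil–Sen + Mann–Kendall, binned OLS, significance tiers, weighted KDE |
| `fluvialfire.propagation` | DO-sag detection, biexponential decay fit, threshold-crossing extent, Horton order model |
| `fluvialfire.reporting` | extent-equals-within-burn upscaling, bootstrap CI, run report |
| `fluvialfire.network` / `types` / `io` | Strahler ordering, domain containers, GeoJSON/CSV readers and writers |

## CLI

```sh
fluvialfire simulate  --seed 1 --config config.json --outdir run/
fluvialfire slba      --network run/network.geojson --scars run/scars.geojson \
                      --ecoregions run/ecoregions.geojson --min-area 4.1 --outdir run/
fluvialfire trends    --summary run/annual_summary.csv --impacts run/fire_impacts.csv --outdir run/
fluvialfire propagate --series run/do_series.csv --threshold 0.5 --rl 2 --l1 1.3 --outdir run/
fluvialfire report    --summary run/annual_summary.csv --network run/network.geojson \
                      --ecoregions run/ecoregions.geojson \
                      --propagation-json run/propagation.json --out run/report.json
```

The config is JSON or TOML; see `tests/test_io_cli.py::CONFIG` for a complete
example. Key outputs: `fire_impacts.csv`, `annual_summary.csv`, `trends.csv`,
`regressions.csv`, `sag_events.csv`, `decay_fit.json`, `propagation.json`,
`report.json`.

## Notes

- Fires with burned area exactly at the 4.1 km² threshold are retained
  (removal is strictly below).
- Per-fire burned area defaults to the severity-filtered footprint area;
  `area_mode="perimeter"` reports the raw perimeter area instead.
- The decay model falls back to a single exponential when the second
  component is unidentifiable (covariance singular at the bound).
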