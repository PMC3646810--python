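# sealdive

Habitat-linked dive classification and behavioural transition analysis for
biologging tag data (GPS surface fixes + time-depth dive records), with a
synthetic tag-data simulator for testing every stage without field data.

The pipeline:

1. **simulate** — generate co-registered bathymetry/sediment rasters (ESRI
   ASCII grids) and per-seal fix/dive tables from a correlated random walk
   with surface-conditional GPS fix attempts.
2. **locate** — keep fixes with ≥ 5 satellites, interpolate a lon/lat for
   every dive (linear in time at the dive's temporal midpoint), and compute
   the interpolated-location error bound
   `(s_max·t̄ − d̄) / n̄` with `n̄ = t̄ / (mean dive + mean surface duration)`.
3. **annotate** — attach charted water depth and pooled sediment class
   (fine = mud/sand, coarse = gravel/mixed, rock = rock/till, else
   unclassified) by containing-cell raster lookup, plus a day/night flag from
   NOAA solar geometry (zenith 90.833°, all times UTC).
4. **classify** — charted depth < 50 m → *shallow*; otherwise the proximity
   ratio (max dive depth / charted depth) < 0.95 → *pelagic*, ≥ 0.95 →
   *benthic*. A binned diagnostic reports the proportion of ratios > 1 per
   5 m depth bin.
5. **transitions** — per-seal joint pair-frequency matrices over consecutive
   dives (dive type and sediment; entries of each matrix sum to 1), averaged
   across seals with each seal weighted equally; dispersion is the sample SD
   (variance switchable).
6. **summarize** — pelagic-dive frequency per seal × sediment × diel cell and
   an OLS fit of frequency on sediment + diel + individual with sequential
   (type-I) ANOVA.

## CLI

```sh
sealdive simulate --out data/ --seals 8 --days 7 --seed 7
sealdive run-all --data data/ --out results/
```

`run-all` chains locate → annotate → classify → transitions → summarize and
writes `run_log.json` with full record accounting (input count = output count
+ logged drops, per stage). Stages can also be run individually; see
`sealdive <stage> --help`. Key flags: `--min-satellites`, `--shallow-cutoff`,
`--benthic-ratio`, `--denominator {all,deep}` (whether shallow dives enter the
frequency denominator), `--dispersion {sd,var}`.

## Data formats

- `fixes.csv`: `seal_id, timestamp, lon, lat, n_satellites` (ISO-8601 UTC).
- `dives.csv`: `seal_id, start_time, end_time, max_depth_m, duration_s`.
- `truth.csv`: `dives.csv` columns + `true_lon, true_lat, true_type`
  (simulator ground truth, withheld from the pipeline).
- Rasters: ESRI ASCII grid (`.asc`), depth in metres **positive down**.

### Using real raster exports

GEBCO stores elevation (negative at sea): negate values before use so depth
is positive down. EUNIS-style sediment maps should be reclassified to the
integer codes `0` unclassified, `1` fine, `2` coarse, `3` rock (string labels
such as "mud", "gravel", "till" are pooled automatically when annotating from
a table). Both rasters must share grid geometry.
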