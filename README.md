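# isoassign

Isoscape calibration and probability-of-origin assignment for stable-hydrogen
isotope (δ²H) data from keratin tissues, plus the split-half cross-validation
machinery used to evaluate calibrations.

The package covers the full workflow used in waterfowl moult-origin studies:

1. **Rasters** (`isoassign.grid`) — a lat/lon, north-up, cell-center
   registered grid model with GeoTIFF and plain-text I/O, tile mosaicking,
   bilinear resampling, polygon/extent masking, and point extraction.
2. **Synthetic data** (`isoassign.synthetic`) — seeded generators for
   gradient isoscapes with uncertainty surfaces and site-clustered
   known-origin cohorts (`d2h_f = a + b·d2h_p + noise`, optional shifted
   outliers), plus a truth-recovery harness.
3. **Calibration** (`isoassign.calibration`) — per-site 1.5×IQR outlier
   fences, record/isoscape pairing with global non-overlap exclusion, OLS
   calibration (intercept, slope, SD of residuals, adjusted r²), and
   feather-space isoscape prediction.
4. **Assignment** (`isoassign.assignment`) — per-individual normalized
   normal-density probability-of-origin surfaces with combined calibration +
   isoscape error (`σ_c = sqrt(sd_resid² + (slope·σ_iso)²)`), odds-ratio
   origin regions (2:1 → upper 66.6 % of probability), region stacking, and
   spherical centroid distances.
5. **Validation** (`isoassign.validation`) — repeated split-half
   cross-validation scoring accuracy (true cell inside the region),
   precision (region cells / working cells), and minimum great-circle
   distance for inaccurate birds.

## CLI

The `isoassign` entry point exposes four commands driven by a flat
`key = value` config file (flags override config keys):

```sh
isoassign simulate  --config sim.cfg  --out out/sim     # isoscape + cohort
isoassign calibrate --config cal.cfg  --out out/cal     # calibration table
isoassign assign    --config asn.cfg  --out out/asn     # regions + stack
isoassign validate  --config val.cfg  --out out/val     # CV iteration CSV
```

Every run writes `resolved_config.txt` and `run.log` (seeds, exclusions)
into the output directory. Odds ratios are accepted as `2:1` strings or
fractions. See `tests/test_cli.py` for complete config examples.

Example — simulate then cross-validate:

```sh
cat > sim.cfg <<'EOF'
n_rows = 100
n_cols = 100
west = -130
north = 60
cell_width = 0.25
cell_height = 0.25
value_north = -160
value_south = -20
noise_sd = 5
smoothing_radius = 1
n_sites = 200
birds_per_site = 5
residual_sd = 15
seed = 1
EOF
isoassign simulate --config sim.cfg --out out/sim
cat > val.cfg <<'EOF'
records = out/sim/records.csv
isoscape = out/sim/isoscape.txt
iterations = 25
seed = 2
EOF
isoassign validate --config val.cfg --out out/val
```

## File formats

- Grids: single-band float GeoTIFF (pixel-scale/tiepoint/nodata tags) or a
  plain-text dialect — one header line
  `n_rows n_cols west north cell_width cell_height nodata` followed by data
  rows north→south.
- Records: CSV with columns
  `id,dataset,species,guild,age,site_id,lon,lat,d2h_f,truth_d2h_p,is_outlier`
  (the last two are generator bookkeeping and may be empty).
- Masks: GeoJSON polygons or `mask_bounds = west,south,east,north` extents.

All computation stays in geographic lon/lat (WGS84); distances use the
haversine formula with R = 6371 km.
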