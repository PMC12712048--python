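# burnzones

Build a wildfire burn-zone **disaster** dataset by harmonizing multi-source
wildfire incident records, applying harm criteria, attaching burn-zone
geometry, and classifying community proximity.

The pipeline stages:

1. **synthetic** — generate a seeded synthetic "fire world" (counties,
   towns, vegetation/housing grids, ground-truth fires) and render it into
   three incident-source flavors (`ics209`, `redbooks`, `fmag`) and three
   perimeter flavors (`mtbs`, `fired`, `nifc`), faithfully emulating each
   source's schema quirks: era-dependent missing fields (no civilian
   fatality breakdown 2000–2013; a combined damaged/destroyed count
   2007–2009), large-fire inclusion thresholds, regional size cutoffs,
   name/date noise, and missing identifiers.
2. **standardize** — USPS-abbreviation name normalization, gazetteer-based
   county canonicalization (including the "LA" alias), multi-dialect date
   parsing, removal of pre-2000 and non-fire rows with a rejection log.
3. **linkage** — cross-source fuzzy matching (county overlap + ignition
   dates within 30 days + Jaro-Winkler name distance ≤ 0.25 with prefix
   factor 0.1), connected-component clustering, and precedence-based
   conflict resolution (the Redbooks-flavor value wins on counts and
   dates; complexes aggregate member fires).
4. **criteria** — harm criteria with era fallbacks: ≥ 1 civilian fatality
   (or any fatality for 2000–2013), ≥ 1 destroyed structure (or ≥ 1
   combined damaged/destroyed for 2007–2009), or a federal
   fire-assistance declaration.
5. **geolink** — tiered geometry attachment: shared interagency ID; name /
   location / date match to the large-fire perimeter flavor;
   point-of-origin match to the nameless flavor; name / location / year
   match to the year-only flavor; then circular-buffer, point-only, and
   county-only fallbacks.
6. **community** — smooth the gridded population into a density surface
   (uniform 300-m moving average), buffer each burn zone 10 km (< 1,000
   acres or point) or 20 km (≥ 1,000 acres), flag max smoothed density
   ≥ 96 people/km², overlay the raw geometry on the wildland-urban
   interface layer (intermix / interface / both / none), and combine both
   into the community flag.
7. **report** — final GeoJSON (null geometry allowed) + data dictionary,
   summary tables, percent shares (half-up, one decimal), and the
   Mann-Kendall trend statistic with tie-corrected variance.

Everything is deterministic for a fixed config and seed, and all I/O is
plain text (CSV, GeoJSON, ESRI ASCII grids).

## CLI

```sh
burnzones run --config cfg.toml --seed 7 --workdir out/
```

Stage subcommands (`simulate`, `clean`, `link`, `criteria`, `geolink`,
`community`, `summarize`) share the same working directory and cached
artifacts. A minimal config:

```toml
seed = 7

[simulation.fires]
n_fires = 200

[match]
jw_max = 0.25
date_window_days = 30

[community]
density_threshold = 96.0
small_buffer_m = 10000.0
large_buffer_m = 20000.0
```

Outputs land in the working directory: raw source CSVs, cleaned events +
rejection log, cluster membership, geometry assignments, the final
`disasters.geojson` (+ `disasters.dictionary.md`), summary tables, and an
audit report (`audit.json` / `audit.md`) that verifies the disaster
definition, the community-flag identity, and stage record-count
conservation.

## Library use

```python
from burnzones import PipelineConfig, run_pipeline

cfg = PipelineConfig()
cfg.simulation.fires.n_fires = 500
cfg.seed = 17
result = run_pipeline(cfg, "out/")
disasters = [r for r in result.records if r.is_disaster]
```
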