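# vectorops

Road-network analysis for planning mosquito-control service delivery:

- **road_network** — undirected road graph (km impedance), point snapping
  with a search tolerance (virtual nodes at perpendicular projections),
  Dijkstra shortest paths with deterministic tie-breaking, distance
  matrices. Readers/writers for GeoJSON LineStrings and node/edge CSV.
- **census_attributes** — neighborhood demand model: population,
  households, a housing condition index (HCI, 0 = excellent .. 1 = very
  poor, mean of normalized roof/wall/floor grades), dengue cases and
  incidence per 10,000.
- **service_areas** — bin neighborhoods by driving distance to the
  nearest active hub (default cutoffs 0.5 / 1 / 3 / 5 km, upper-closed)
  and summarize population, mean HCI, and pooled incidence per bin.
- **route_costing** — closest-facility routing plus a capacitated trip
  model: `ceil(households / 25)` trips, each costed as a full round trip
  at $0.61/L and 5.53 km/L; cost-class summaries (quintiles or explicit
  edges).
- **location_allocation** — weighted p-median siting of k hubs from a
  candidate pool under four weighting scenarios (uniform, population,
  dengue cases, HCI); exact enumeration by default, seeded Teitz–Bart
  vertex substitution for large pools; scenario-vs-baseline comparison
  metrics (mean cost reduction, cheapest-class population change).
- **synthetic_city** — deterministic generator of a connected
  jittered-grid city with ~254 neighborhoods, HCI worsening toward the
  periphery, centrally concentrated dengue cases, two central hubs, and
  eight quadrant-stratified candidate subcenters.
- **pipeline / cli** — end-to-end orchestration with validation,
  logging, and a text report bundle (CSV/JSON/GeoJSON).

## CLI

```sh
# full pipeline on a synthetic city
vectorops run --synth --seed 7 --out out/

# from files
vectorops run --network net.geojson --neighborhoods nbhds.csv \
    --facilities facilities.geojson --out out/

# other stages
vectorops synth --seed 7 --out city/          # write synthetic inputs
vectorops validate --synth                    # structural input checks
vectorops allocate --synth --mode hci --out out/
```

All knobs (snap tolerance, bin cutoffs, cost model, allocation
scenarios, cost-class edges) can be set in a JSON config passed via
`--config cfg.json`; see `vectorops.pipeline.RunConfig.from_dict` for
the schema. Outputs: `neighborhoods_out.csv`, `bins_summary.csv`,
`cost_classes.csv`, `routes.geojson`, `allocation_<mode>.json`,
`comparison_<mode>.json`, plus an `unreachable.csv` sidecar and a
config echo. Identical config + seed reproduces the bundle
byte-for-byte.

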