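# tierplan

Planning toolkit for **tiered national diagnostic networks**, built around the
six-tier service-delivery model used to organise CD4 testing for a national
HIV programme: point-of-care testing at remote clinics (Tier 1), POC hubs
consolidating ~8–10 clinics (Tier 2), community laboratories (Tier 3),
district laboratories (Tier 4), high-volume metro laboratories (Tier 5) and a
coordinating reference tier (Tier 6).

It is written for health-systems analysts and laboratory-network planners who
need to answer, from a facility registry and a laboratory registry:

* **Coverage** — which clinics fall outside every laboratory's *service
  precinct* (a catchment circle, default radius 100 km), and which areas are
  over-serviced by co-located laboratories?
* **Tiering** — given each laboratory's assigned daily workload
  `d = annual volume / working days`, which service tier does it belong to
  (inclusive breaks at 10, 40, 150 and 300 samples/day), is its instrument
  capacity adequate, and which higher-tier laboratory is the *parent* that
  supports each Tier-1/2 site?
* **Placement** — where should new Tier-1/2/3 services go to close coverage
  gaps?  Formalised as greedy maximal covering over general-pathology
  laboratories (candidate hosts) plus on-site POC for the remainder.
* **Cost** — what does each national expansion scenario cost?  Per-tier annual
  volumes ×  per-test prices (default USD 32.32 / 15.88 / 7.42 / 6.24 / 5.37
  for T1–T5), in exact integer-cent arithmetic, comparing *widespread POC*
  (the whole decentralised extension tested at Tier-1 prices) against the
  *full tiered model* (each tier at its own price):

  `saving = V_T2·(c_T1 − c_T2) + V_T3·(c_T1 − c_T3)`

* **Turnaround** — district-level banding of the fraction of results
  authorised within a threshold (default 48 h), and before/after comparisons
  when a local laboratory is installed.

Because real facility registries are rarely shareable, the package includes a
seeded synthetic generator (`tierplan.synthetic`) that reproduces the
*structure* of a country-scale network — 52 districts in 9 provinces, ~4,756
facilities with a realistic category mix, heavy-tailed annual volumes summing
exactly to ~3.9 M tests, ~65 CD4 laboratories concentrated in metros, 14
districts with no local laboratory — so every stage is testable end to end.

## Worked example

```python
import tierplan as tp

schedule = tp.load_tier_schedule()          # published tier parameters
full = tp.full_itsdm_scenario(schedule)     # each tier at its own price
poc = tp.widespread_poc_scenario(schedule)  # extension all at POC prices
print(full.to_frame().to_string(index=False))
print(f"full ITSDM total: ${full.total_usd:,.2f}  (R{full.total_zar:,.2f})")
print(f"widespread POC total: ${poc.total_usd:,.2f}")
comparison = tp.compare_scenarios(poc, full, schedule)
print(f"saving: ${comparison.saving_usd:,.2f}  (R{comparison.saving_zar:,.2f})")
```

prints

```
tier  annual_volume  unit_cost_usd  annual_cost_usd
  T1          78000          32.32        2520960.0
  T2         117000          15.88        1857960.0
  T3         390000           7.42        2893800.0
  T4         585000           6.24        3650400.0
  T5        2730000           5.37       14660100.0
full ITSDM total: $25,583,220.00  (R281,415,420.00)
widespread POC total: $37,217,700.00
saving: $11,634,480.00  (R127,979,280.00)
```

i.e. extending coverage by distributing the 585,000-test decentralised volume
across Tiers 1–3 instead of pricing it all at the point-of-care rate saves
$11.6 M (R128 M at R11/USD) per year.

The spatial pipeline runs the same way from registries (or the generator):

```python
facilities, labs, districts = tp.generate_network(tp.NetworkConfig(seed=1))
cd4 = tp.cd4_labs(labs)
assignments = tp.assign_nearest(facilities, cd4, schedule)
report = tp.coverage_report(assignments, facilities, cd4, schedule)
tiers = tp.tier_labs(assignments, facilities, cd4, schedule)
```

Every stage is also exposed on the `tierplan` command line (`simulate`,
`assign`, `tier`, `place`, `cost`, `report-tat`); registries are plain CSV or
GeoJSON.

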