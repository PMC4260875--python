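# Methods

This note documents the models behind `tierplan`: what is computed, the
assumptions and defaults, what the synthetic generator does and does not
emulate, and the numerical conventions.

## The tiered service model

A national testing network is described by two registries: referring health
**facilities** (id, category, district, WGS84 coordinates, annual test
volume) and **laboratories** (id, coordinates, district, instrument
capacity, a flag for general-pathology sites that could host new services).
The `TierSchedule` collects the service parameters:

| parameter | default | meaning |
|---|---|---|
| `volume_breaks` | 10, 40, 150, 300, ∞ | inclusive daily-volume upper bounds for Tiers 1–5 (samples/day) |
| `clinic_count_ranges` | 1, ≤10, 11–50, 51–100, >100 | advisory referring-clinic counts per tier |
| `instrument_capacity` | 10, 30, 150, 384, 768, 1536 | maximum instrument throughput per 8-h day, Tiers 1–6 |
| `cost_per_test_cents` | 3232, 1588, 742, 624, 537 | per-test price, Tiers 1–5 (US cents) |
| `superlab_break` | 600 /day | combined demand above which co-located T4/T5 labs are consolidation candidates |
| `working_days_per_year` | 260 | converts annual volume to daily demand (5-day weeks; configurable because many primary-care clinics operate 4 days/week) |
| `radius_km` | 100 | service-precinct radius |
| `t2_radius_km` | 20 | POC-hub catchment radius |
| `zar_per_usd` | 11 | exchange rate for ZAR reporting |

Source descriptions of the tier boundaries mix strict and inclusive
operators (and give conflicting Tier-5 thresholds); we normalise to a single
rule — **inclusive upper bounds**, so T1 = [0, 10], T2 = (10, 40],
T3 = (40, 150], T4 = (150, 300], T5 = (300, ∞) — and make every break
configurable.  Similarly the advisory clinic counts are described
inconsistently across sources; the tabulated 11–50 / 51–100 / >100 ranges
are taken as canonical, and classification keys on **volume only**, with the
clinic count recorded as a consistency annotation (`clinic_count_consistent`),
never as a constraint.

## Coverage and assignment

Distances are great-circle (haversine) kilometres on the IUGG mean-Earth
sphere (R = 6371.0088 km).  Precinct radii of 100–400 km are short enough
that a planar approximation differs by well under 1%; an equirectangular
`method="planar"` is provided for comparison and flagged in report metadata,
but geodesic distance is the default and the defensible reading at these
scales.

Each facility is assigned to its **nearest** laboratory (capacity is
reported, not enforced — assignment is purely geometric).  Ties within
10⁻⁹ km resolve to the lexicographically smallest laboratory id, making the
assignment deterministic and invariant to registry row order.  A facility is
*covered* when its assignment distance is at most `radius_km`.  Coverage is
reported both facility-weighted and volume-weighted, since the two answer
different planning questions.  Laboratories lying within one precinct radius
of each other are flagged as over-service (consolidation) candidates.

## Tiering, support graph, super-laboratories

A laboratory's daily demand is its assigned annual volume divided by
`working_days_per_year`.  Zero-demand sites classify as Tier 1 with a
warning rather than an error (idle sites are real).  `capacity_check`
compares `instrument_capacity[tier] × n_instruments` against daily demand;
negative margins are flagged, positive margins quantify the redundancy
networks deliberately retain for growth and instrument downtime.

Every Tier-1/2 site is linked to its nearest Tier-3+ laboratory — the
*parent* responsible for quality control, training and maintenance support.
The graph is a forest by construction (one parent per child); if no
qualifying parent exists the orphaned sites are listed in the error.
Super-laboratory candidates are connected components (not cliques) of
T4/T5 laboratories under the within-radius adjacency whose combined demand
exceeds `superlab_break`; components, because consolidation is transitive
through a shared metro area.

## Placement of new sites

The historical exercise this formalises was manual map inspection; we use
**greedy maximal covering**, which is transparent, deterministic and carries
the classical ln n + 1 approximation bound (verified in tests against
exhaustive optima on small instances).  Candidates are general-pathology
laboratories, each considered in two roles: a Tier-2 hub role covering
`t2_radius_km` and a community-laboratory role covering `radius_km`.  Each
iteration selects the candidate-role newly covering the most uncovered
facilities; ties break on covered volume, then the smaller role radius
(a hub suffices), then the smaller id.  Selection stops when the best gain
falls below `min_gain` (default 2), so isolated single clinics become
on-site Tier-1 POC services rather than dedicated hubs.  The tier finally
proposed for a chosen site comes from classifying the daily volume it would
absorb — the role only sets the catchment radius — so a low-volume pick in
the wide role may still be proposed as a Tier-2 service.

## Cost scenarios

All money is integer US cents and all volumes integer tests/year, so totals
are exact and independent of summation order.  The per-tier allocation of a
national annual volume uses **largest-remainder (Hamilton) apportionment**
(ties to the smallest index), which preserves the total exactly; the default
shares are 2/3/10/15/70% of 3.9 M tests.  Two named scenarios:

* **widespread_poc** — the whole Tier-1–3 extension volume priced at the
  Tier-1 POC rate (no hub or community services), plus T4/T5 at their own
  rates;
* **full_itsdm** — every tier at its own rate.

Their difference obeys the identity
`saving = V_T2·(c_T1 − c_T2) + V_T3·(c_T1 − c_T3)`, which the tests check
both symbolically-derived and end-to-end.  Tier 6 carries no per-test price;
routing volume to it is an error.  ZAR amounts are exact integer products at
integral exchange rates.  Rounding to headline precision happens only at
report time, never inside computation.  With the default schedule the
computed ZAR saving is R127,979,280 (= $11,634,480 × 11); published summary
tables print a slightly smaller ZAR figure that is inconsistent with their
own USD saving and exchange rate, so `tierplan` always reports the computed
conversion.

## Turnaround model

A record splits turnaround into the **pre-analytic** component (dispatch to
laboratory registration) and the **laboratory-to-result (LTR)** component
(registration to authorization).  District banding reports the fraction of
records with LTR time within a threshold (default 48 h, with 24 h as a
strict mode), mapped onto contiguous percentage bands with edges at 35, 85
and 95% — published legend bands have gaps (34–35%, 80–86%); we normalise to
contiguous edges so every fraction maps to exactly one band, keeping
recognisable labels.

## The synthetic generator

`generate_network` emulates the *statistical structure* a national CD4
network analysis relies on, not any real geography:

* 52 districts on a jittered grid over a country-sized rectangular extent
  (~1,600 × 1,400 km), grouped into 9 provinces; ~15% of districts are
  metros (denser, higher-volume), and 14 non-metro districts host no CD4
  laboratory — their samples refer into adjacent districts, 150–250 km away.
* 4,756 facilities with the category mix 19% mobile / 4% satellite / 65%
  primary-care / 1% community day centre / 5% community health centre / 5%
  district hospital / 1% regional hospital, apportioned exactly and
  permuted; positions are a two-component mixture per district (tight
  central cluster + dispersed rural).
* Annual volumes are lognormal (σ = 1.5) with category multipliers (mobile
  0.04 ... regional hospital 6) and a ×3 metro multiplier, truncated below
  at one test/year and apportioned by largest remainder so the national
  total equals 3,900,000 **exactly**.  The resulting spread runs from under
  5 to far above 17,000 tests/year, and primary-care clinics carry roughly
  two-thirds of national volume.
* 65 CD4 laboratories are placed in the busiest eligible districts (at
  least one each, extras by volume), with instrument capacity set to
  1.15–1.4 × home-district demand — the deliberate redundancy real networks
  keep; 195 general-pathology-only sites (capacity 0) are spread over all
  districts as placement candidates.

Calibrated this way, a default network leaves ~10% of facilities outside
every 100 km precinct (seed-swept band 0.07–0.13), and districts without a
local laboratory have systematically longer assignment distances and worse
TAT banding.  The greedy placement plan on these networks absorbs ~5% of
national volume into new decentralised sites — smaller than the 15%
extension share a real national exercise allocated, because synthetic remote
districts are low-volume by construction; the 15% share is therefore used as
the cost model's allocation default, not asserted of the generator.

The TAT simulator draws, per sample, `pre = base + distance/speed +
U(0, batching)` and `LTR = lognormal(median, σ) + overload`, with overload
proportional to a laboratory's fractional demand/capacity excess.  Defaults
(courier 30 km/h, base 1.5 h, batching 0–4 h, LTR median 16 h, σ = 0.5,
penalty 24 h per unit excess) were chosen once so that a remote district
referring ~400 km away sees a pre-analytic median in the 15–48 h range that
drops below 5 h when a local laboratory cuts the distance to ~30 km — the
qualitative contrast reported when decentralised community laboratories were
actually installed.  Draws occur in fixed record order, so same-seed runs
with modified networks are pairwise comparable.

**What passing tests do not show:** the generator has no road networks,
population rasters, prevalence surfaces or real coordinates, so absolute
distances, courier times and the spatial pattern of gaps are stylised;
results on synthetic networks validate the *pipeline logic* (assignment,
tiering, placement, costing, banding), not any real country's coverage
figures.  Problem sizes in the test suite and acceptance script are the
full default network (4,756 facilities, 65 laboratories, 20,000 TAT
records), which runs in well under a minute.

## Numerical conventions and degenerate inputs

* Coordinates are validated to |lat| ≤ 90, |lon| ≤ 180; registries reject
  duplicate ids; missing annual volumes become 0 with a warning (zero is
  conservative for capacity planning).
* Assignment ties: 10⁻⁹ km tolerance, smallest id.  Apportionment ties:
  smallest index.  Greedy ties: volume, then radius, then id.
* Empty uncovered set → empty placement plan (not an error).  Empty
  laboratory registry → error.  A district absent from a TAT record set is
  reported with n = 0 and no band.
* Referral-source shares quoted in the source material sum to 103%; the
  generator treats composition shares as a normalised configurable vector
  rather than guessing which figure is wrong.
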