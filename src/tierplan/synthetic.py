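"""Synthetic country-scale facility/laboratory networks and TAT records.

The generator emulates the statistical structure of a national CD4
referral network — 52 districts in 9 provinces, ~4,756 referring health
facilities with a fixed category mix, ~65 testing laboratories
concentrated in metropolitan districts, a configurable number of
districts with no local CD4 laboratory, and heavy-tailed per-facility
annual volumes (from a handful of tests per year at remote mobile clinics
to >17,000 at inner-city clinics) rescaled so the national total is met
exactly.  Geography is abstract: district centroids sit on a jittered
grid over a rectangular country-sized extent, and facilities are drawn
from a two-component (tight metro cluster + dispersed rural) mixture per
district.  No real coordinates, road networks or prevalence surfaces are
used.

Turnaround records are simulated per sample: the pre-analytic component
is courier base delay + distance/speed + a batching draw, and the
laboratory component is a lognormal processing draw plus an overload
penalty where assigned demand exceeds instrument capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .costing import largest_remainder_apportion
from .errors import ConfigError, ValidationError
from .model import CATEGORIES

#: Facility category proportions (national facility-classification mix).
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "mobile": 0.19,
    "satellite": 0.04,
    "phc": 0.65,
    "cdc": 0.01,
    "chc": 0.05,
    "district_hospital": 0.05,
    "regional_hospital": 0.01,
}

#: Relative mean annual volume per facility category.  Hospitals refer far
#: more tests than mobile clinics; PHC clinics are the reference level and,
#: at 65% of facilities, carry roughly two-thirds of national volume.
DEFAULT_CATEGORY_VOLUME_MULT: dict[str, float] = {
    "mobile": 0.04,
    "satellite": 0.4,
    "phc": 1.0,
    "cdc": 1.5,
    "chc": 2.0,
    "district_hospital": 2.5,
    "regional_hospital": 6.0,
    "tertiary_hospital": 10.0,
    "parastatal": 0.5,
}


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the synthetic national network."""

    n_districts: int = 52
    n_provinces: int = 9
    n_facilities: int = 4756
    n_labs: int = 65
    #: General-pathology laboratories with no CD4 instrument: candidates for
    #: hosting new Tier-2/3 services.
    n_general_labs: int = 195
    total_annual_tests: int = 3_900_000
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    #: Share of districts designated metropolitan.
    metro_fraction: float = 0.15
    #: Districts (non-metro) with no local CD4 testing laboratory.
    n_lab_free_districts: int = 14
    #: Facility-count weight of a metro district relative to an ordinary one.
    metro_facility_weight: float = 6.0
    #: Facility-count weight of a remote lab-free district (sparsely served).
    remote_facility_weight: float = 0.5
    #: Lognormal sigma of per-facility annual volumes (heavy-tail shape).
    volume_dispersion: float = 1.5
    category_volume_mult: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_VOLUME_MULT)
    )
    #: Mean-volume multiplier for facilities in metro districts.
    metro_volume_mult: float = 3.0
    #: Country extent, decimal degrees (lon_min, lon_max, lat_min, lat_max).
    extent: tuple[float, float, float, float] = (16.5, 32.9, -34.8, -22.1)
    metro_cluster_sigma_deg: float = 0.06
    rural_sigma_deg: float = 0.45
    #: Share of a district's facilities in the tight central cluster.
    cluster_share_metro: float = 0.7
    cluster_share_rural: float = 0.3
    #: Instrument-capacity redundancy band over home-district daily demand.
    capacity_redundancy: tuple[float, float] = (1.15, 1.4)
    working_days_per_year: int = 260
    seed: int = 0

    def normalized_mix(self) -> dict[str, float]:
        bad = set(self.category_mix) - set(CATEGORIES)
        if bad:
            raise ConfigError(f"unknown facility categories in mix: {sorted(bad)}")
        total = sum(self.category_mix.values())
        if total <= 0:
            raise ConfigError("category_mix must have positive total")
        mix = {k: v / total for k, v in self.category_mix.items() if v > 0}
        assert abs(sum(mix.values()) - 1.0) < 1e-9
        return mix

    def validate(self) -> "NetworkConfig":
        for name in ("n_districts", "n_provinces", "n_facilities", "n_labs",
                     "total_annual_tests"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_labs > self.n_facilities:
            raise ConfigError("more laboratories than facilities is infeasible")
        if self.n_provinces > self.n_districts:
            raise ConfigError("more provinces than districts is infeasible")
        n_metro = round(self.metro_fraction * self.n_districts)
        if n_metro + self.n_lab_free_districts > self.n_districts:
            raise ConfigError("metro and lab-free districts exceed district count")
        self.normalized_mix()
        return self


def _district_grid(cfg: NetworkConfig, rng: np.random.Generator) -> pd.DataFrame:
    lon0, lon1, lat0, lat1 = cfg.extent
    aspect = (lon1 - lon0) * math.cos(math.radians((lat0 + lat1) / 2)) / (lat1 - lat0)
    ncols = max(1, round(math.sqrt(cfg.n_districts * aspect)))
    nrows = math.ceil(cfg.n_districts / ncols)
    dlon, dlat = (lon1 - lon0) / ncols, (lat1 - lat0) / nrows
    rows = []
    width = len(str(cfg.n_districts))
    for k in range(cfg.n_districts):
        r, c = divmod(k, ncols)
        clon = lon0 + (c + 0.5) * dlon + rng.uniform(-0.15, 0.15) * dlon
        clat = lat0 + (r + 0.5) * dlat + rng.uniform(-0.15, 0.15) * dlat
        rows.append(
            {
                "id": f"D{k + 1:0{width}d}",
                "province": f"P{k * cfg.n_provinces // cfg.n_districts + 1}",
                "centroid_lat": clat,
                "centroid_lon": clon,
            }
        )
    return pd.DataFrame(rows)


def generate_network(
    config: NetworkConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (facilities, laboratories, districts) registries.

    Deterministic for a given config (the config carries the seed).  The
    laboratory registry contains both CD4 testing laboratories
    (``instrument_capacity_per_day > 0``) and general-pathology-only sites
    (capacity 0) that serve as placement candidates; filter with
    :func:`tierplan.model.cd4_labs` where only the testing network matters.
    Facility annual volumes are heavy-tailed lognormal draws apportioned by
    largest remainder so they sum exactly to ``total_annual_tests``.
    """
    cfg = (config or NetworkConfig()).validate()
    rng = np.random.default_rng(cfg.seed)

    districts = _district_grid(cfg, rng)
    n_metro = round(cfg.metro_fraction * cfg.n_districts)
    metro_idx = rng.choice(cfg.n_districts, size=n_metro, replace=False)
    is_metro = np.zeros(cfg.n_districts, dtype=bool)
    is_metro[metro_idx] = True
    non_metro = np.flatnonzero(~is_metro)
    lab_free_idx = rng.choice(non_metro, size=cfg.n_lab_free_districts, replace=False)
    is_lab_free = np.zeros(cfg.n_districts, dtype=bool)
    is_lab_free[lab_free_idx] = True
    districts["is_metro"] = is_metro
    districts["has_cd4_lab"] = ~is_lab_free  # provisional; finalised below

    # --- facilities per district -----------------------------------------
    dist_weights = np.where(
        is_metro,
        cfg.metro_facility_weight,
        np.where(is_lab_free, cfg.remote_facility_weight, 1.0),
    )
    n_fac_per_district = largest_remainder_apportion(cfg.n_facilities, dist_weights)

    # --- categories: exact apportionment, randomly permuted ---------------
    mix = cfg.normalized_mix()
    cat_names = list(mix)
    cat_counts = largest_remainder_apportion(cfg.n_facilities, [mix[c] for c in cat_names])
    categories = np.repeat(cat_names, cat_counts)
    categories = categories[rng.permutation(cfg.n_facilities)]

    # --- positions ---------------------------------------------------------
    lon0, lon1, lat0, lat1 = cfg.extent
    district_of = np.repeat(np.arange(cfg.n_districts), n_fac_per_district)
    clat = districts["centroid_lat"].to_numpy()[district_of]
    clon = districts["centroid_lon"].to_numpy()[district_of]
    cluster_share = np.where(
        is_metro[district_of], cfg.cluster_share_metro, cfg.cluster_share_rural
    )
    tight = rng.random(cfg.n_facilities) < cluster_share
    sigma = np.where(tight, cfg.metro_cluster_sigma_deg, cfg.rural_sigma_deg)
    lat = np.clip(clat + rng.normal(0, 1, cfg.n_facilities) * sigma, lat0, lat1)
    lon = np.clip(clon + rng.normal(0, 1, cfg.n_facilities) * sigma, lon0, lon1)

    # --- heavy-tailed volumes, exact national total ------------------------
    mult = np.array([cfg.category_volume_mult[c] for c in categories])
    mult = mult * np.where(is_metro[district_of], cfg.metro_volume_mult, 1.0)
    raw = mult * rng.lognormal(mean=0.0, sigma=cfg.volume_dispersion, size=cfg.n_facilities)
    raw *= cfg.total_annual_tests / raw.sum()  # pre-scale to test units
    raw = np.maximum(raw, 1.0)  # truncate the lower tail at one test/year
    volumes = np.array(
        largest_remainder_apportion(cfg.total_annual_tests, raw), dtype=np.int64
    )

    width = len(str(cfg.n_facilities))
    facilities = pd.DataFrame(
        {
            "id": [f"F{k + 1:0{width}d}" for k in range(cfg.n_facilities)],
            "name": [f"Facility {k + 1}" for k in range(cfg.n_facilities)],
            "category": categories,
            "district_id": districts["id"].to_numpy()[district_of],
            "latitude": lat,
            "longitude": lon,
            "annual_volume": volumes,
        }
    )

    # --- CD4 laboratories ---------------------------------------------------
    district_volume = np.zeros(cfg.n_districts)
    np.add.at(district_volume, district_of, volumes)

    eligible = np.flatnonzero(~is_lab_free)
    eligible = eligible[np.argsort(-district_volume[eligible], kind="stable")]
    labs_per_district = np.zeros(cfg.n_districts, dtype=int)
    n_base = min(len(eligible), cfg.n_labs)
    labs_per_district[eligible[:n_base]] = 1  # busiest eligible districts first
    spare = cfg.n_labs - n_base
    if spare > 0:
        extra = largest_remainder_apportion(spare, district_volume[eligible])
        for d, e in zip(eligible, extra):
            labs_per_district[d] += e

    lab_rows = []
    lab_width = len(str(cfg.n_labs))
    k = 0
    for d in range(cfg.n_districts):
        n_d = labs_per_district[d]
        if n_d == 0:
            continue
        daily_share = district_volume[d] / cfg.working_days_per_year / n_d
        for _ in range(n_d):
            k += 1
            redundancy = rng.uniform(*cfg.capacity_redundancy)
            lab_rows.append(
                {
                    "id": f"L{k:0{lab_width}d}",
                    "latitude": float(
                        np.clip(
                            districts.loc[d, "centroid_lat"] + rng.normal(0, 0.05),
                            lat0,
                            lat1,
                        )
                    ),
                    "longitude": float(
                        np.clip(
                            districts.loc[d, "centroid_lon"] + rng.normal(0, 0.05),
                            lon0,
                            lon1,
                        )
                    ),
                    "district_id": districts.loc[d, "id"],
                    "tier": "unassigned",
                    "instrument_capacity_per_day": max(10, round(daily_share * redundancy)),
                    "offers_general_pathology": bool(rng.random() < 0.8),
                }
            )
    districts["has_cd4_lab"] = labs_per_district > 0

    # --- general-pathology-only sites (Tier-2/3 placement candidates) -------
    gen_weights = np.asarray(n_fac_per_district, dtype=float) + 1.0
    gen_per_district = largest_remainder_apportion(cfg.n_general_labs, gen_weights)
    gen_width = len(str(max(cfg.n_general_labs, 1)))
    g = 0
    for d in range(cfg.n_districts):
        for _ in range(gen_per_district[d]):
            g += 1
            lab_rows.append(
                {
                    "id": f"G{g:0{gen_width}d}",
                    "latitude": float(
                        np.clip(
                            districts.loc[d, "centroid_lat"] + rng.normal(0, 0.2),
                            lat0,
                            lat1,
                        )
                    ),
                    "longitude": float(
                        np.clip(
                            districts.loc[d, "centroid_lon"] + rng.normal(0, 0.2),
                            lon0,
                            lon1,
                        )
                    ),
                    "district_id": districts.loc[d, "id"],
                    "tier": "unassigned",
                    "instrument_capacity_per_day": 0,
                    "offers_general_pathology": True,
                }
            )

    labs = pd.DataFrame(lab_rows)
    districts["annual_volume"] = district_volume.astype(np.int64)
    districts["n_facilities"] = n_fac_per_district
    return facilities, labs, districts


@dataclass(frozen=True)
class TatParams:
    """Parameters of the per-sample turnaround simulation.

    The transport model is a stylised courier process: a fixed dispatch
    delay, travel at constant speed over the assignment distance, and a
    uniform batching wait.  Laboratory processing is lognormal around a
    median, plus a penalty proportional to fractional demand/capacity
    excess at overloaded laboratories.
    """

    courier_speed_km_per_h: float = 30.0
    courier_base_delay_h: float = 1.5
    batching_interval_h: float = 4.0
    lab_processing_median_h: float = 16.0
    lab_processing_sigma: float = 0.5
    overload_penalty_h: float = 24.0
    n_records: int = 20000
    working_days_per_year: int = 260
    seed: int = 0

    def validate(self) -> "TatParams":
        for name in (
            "courier_speed_km_per_h",
            "lab_processing_median_h",
            "lab_processing_sigma",
            "n_records",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("courier_base_delay_h", "batching_interval_h", "overload_penalty_h"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        return self


def generate_tat_records(
    assignments: pd.DataFrame,
    facilities: pd.DataFrame,
    labs: pd.DataFrame,
    params: TatParams | None = None,
) -> pd.DataFrame:
    """Simulate per-sample turnaround records for an assigned network.

    Sample counts per facility are apportioned from ``params.n_records``
    proportionally to annual volume (at least one record per facility), so
    every district is represented.  Draws occur in fixed record order, so
    runs with the same seed but modified distances are pairwise
    comparable.  Raises if any facility lacks an assignment.
    """
    params = (params or TatParams()).validate()
    fac = facilities.merge(
        assignments, left_on="id", right_on="facility_id", how="left"
    )
    missing = fac.loc[fac["lab_id"].isna(), "id"].tolist()
    if missing:
        raise ValidationError(f"facilities without an assignment: {sorted(missing)[:20]}")

    # overload per laboratory: assigned daily demand vs instrument capacity
    demand = (
        fac.groupby("lab_id")["annual_volume"].sum() / params.working_days_per_year
    )
    cap = labs.set_index("id")["instrument_capacity_per_day"]
    overload = {}
    for lab_id, d in demand.items():
        c = cap.get(lab_id, 0)
        excess = max(0.0, d / c - 1.0) if c > 0 else 0.0
        overload[lab_id] = params.overload_penalty_h * excess

    n_per_fac = np.maximum(
        largest_remainder_apportion(
            params.n_records, fac["annual_volume"].to_numpy(float) + 0.5
        ),
        1,
    )
    rng = np.random.default_rng(params.seed)
    n_total = int(n_per_fac.sum())
    fac_idx = np.repeat(np.arange(len(fac)), n_per_fac)

    dist = fac["distance_km"].to_numpy(float)[fac_idx]
    pre = (
        params.courier_base_delay_h
        + dist / params.courier_speed_km_per_h
        + rng.uniform(0.0, params.batching_interval_h, size=n_total)
        if params.batching_interval_h > 0
        else params.courier_base_delay_h + dist / params.courier_speed_km_per_h
    )
    pre = np.asarray(pre, dtype=float)
    penalty = fac["lab_id"].map(overload).to_numpy(float)[fac_idx]
    ltr = (
        rng.lognormal(
            mean=math.log(params.lab_processing_median_h),
            sigma=params.lab_processing_sigma,
            size=n_total,
        )
        + penalty
    )
    width = len(str(n_total))
    return pd.DataFrame(
        {
            "sample_id": [f"S{k + 1:0{width}d}" for k in range(n_total)],
            "facility_id": fac["id"].to_numpy()[fac_idx],
            "district_id": fac["district_id"].to_numpy()[fac_idx],
            "pre_analytic_h": pre,
            "ltr_h": ltr,
            "total_h": pre + ltr,
        }
    )


def with_seed(config: NetworkConfig, seed: int) -> NetworkConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
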