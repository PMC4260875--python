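"""Domain types, configuration and registry I/O.

Registries of health facilities and laboratories are held as pandas
DataFrames with a fixed column contract, validated on read.  Coordinates
are WGS84 decimal degrees stored as (latitude, longitude); GeoJSON output
uses ``[lon, lat]`` order per the GeoJSON specification.

The :class:`TierSchedule` carries the six-tier service parameters: daily
volume breaks separating the tiers, advisory clinic-count ranges,
instrument throughput, per-test prices and the coverage-precinct radius.
Its defaults describe a national CD4 programme with ~3.9M tests/year
routed through point-of-care sites (Tier 1), POC hubs (Tier 2), community
(Tier 3), district (Tier 4) and metro (Tier 5) laboratories, with a
coordinating reference tier (Tier 6) that performs no routine testing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError, SchemaError, ValidationError

#: Health-facility categories (national facility classification).
CATEGORIES: tuple[str, ...] = (
    "mobile",
    "satellite",
    "phc",
    "cdc",
    "chc",
    "district_hospital",
    "regional_hospital",
    "tertiary_hospital",
    "parastatal",
)

TIER_LABELS: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")

FACILITY_COLUMNS: tuple[str, ...] = (
    "id",
    "name",
    "category",
    "district_id",
    "latitude",
    "longitude",
    "annual_volume",
)

LAB_COLUMNS: tuple[str, ...] = (
    "id",
    "latitude",
    "longitude",
    "district_id",
    "tier",
    "instrument_capacity_per_day",
    "offers_general_pathology",
)


@dataclass(frozen=True)
class TierSchedule:
    """Parameters of the tiered service model.

    Tier k (k = 1..5) handles daily sample loads up to ``volume_breaks[k-1]``
    (inclusive upper bounds; Tier 5 is unbounded).  ``cost_per_test_cents``
    holds integer US cents so scenario arithmetic is exact.
    """

    #: Inclusive daily-volume upper bounds for T1..T5 (samples/day).
    volume_breaks: tuple[float, ...] = (10.0, 40.0, 150.0, 300.0, math.inf)
    #: Advisory (lo, hi) referring-clinic counts for T1..T5.
    clinic_count_ranges: tuple[tuple[int, int], ...] = (
        (1, 1),
        (2, 10),
        (11, 50),
        (51, 100),
        (101, 10**9),
    )
    #: Maximum instrument throughput per 8-hour day for T1..T6 (samples/day).
    instrument_capacity: tuple[int, ...] = (10, 30, 150, 384, 768, 1536)
    #: Per-test price for T1..T5 in integer US cents (T6 does no testing).
    cost_per_test_cents: tuple[int, ...] = (3232, 1588, 742, 624, 537)
    #: Combined daily demand above which co-located high-tier labs become
    #: super-laboratory consolidation candidates.
    superlab_break: float = 600.0
    working_days_per_year: int = 260
    #: Service-precinct radius around a testing laboratory (km).
    radius_km: float = 100.0
    #: Catchment radius of a Tier-2 POC hub (km).
    t2_radius_km: float = 20.0
    zar_per_usd: float = 11.0

    @property
    def cost_per_test_usd(self) -> tuple[float, ...]:
        return tuple(c / 100.0 for c in self.cost_per_test_cents)

    def tier_of(self, daily_volume: float) -> int:
        """Tier (1-based) for a daily sample volume, by inclusive upper breaks."""
        if daily_volume < 0:
            raise ValidationError(f"daily_volume must be >= 0, got {daily_volume}")
        for k, brk in enumerate(self.volume_breaks, start=1):
            if daily_volume <= brk:
                return k
        return len(self.volume_breaks)  # unreachable with an inf top break

    def validate(self) -> "TierSchedule":
        breaks = self.volume_breaks
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise ConfigError(f"volume breaks must be strictly increasing, got {breaks}")
        costs = self.cost_per_test_cents
        if any(c2 >= c1 for c1, c2 in zip(costs, costs[1:])):
            raise ConfigError(
                f"per-test costs must strictly decrease from T1 to T5, got {costs}"
            )
        if self.radius_km <= 0 or self.t2_radius_km <= 0:
            raise ConfigError("precinct radii must be positive")
        if not 200 <= self.working_days_per_year <= 365:
            raise ConfigError(
                f"working_days_per_year must lie in [200, 365], got {self.working_days_per_year}"
            )
        if self.zar_per_usd <= 0:
            raise ConfigError("zar_per_usd must be positive")
        if len(self.instrument_capacity) != 6 or len(self.cost_per_test_cents) != 5:
            raise ConfigError("expected 6 instrument capacities (T1-T6) and 5 unit costs (T1-T5)")
        return self


def load_tier_schedule(config: Mapping[str, Any] | str | Path | None = None) -> TierSchedule:
    """Build a :class:`TierSchedule` from a mapping or a YAML file.

    An empty/absent config yields the default schedule.  ``cost_per_test_usd``
    (a 5-vector of USD prices) is accepted and converted to integer cents;
    all other keys map directly onto :class:`TierSchedule` fields.
    """
    if config is None:
        cfg: dict[str, Any] = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)

    if "cost_per_test_usd" in cfg:
        usd = cfg.pop("cost_per_test_usd")
        cfg["cost_per_test_cents"] = tuple(int(round(float(c) * 100)) for c in usd)

    known = TierSchedule.__dataclass_fields__
    unknown = set(cfg) - set(known)
    if unknown:
        raise SchemaError(f"unknown tier-schedule keys: {sorted(unknown)}")
    for key in ("volume_breaks", "instrument_capacity", "cost_per_test_cents"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    if "clinic_count_ranges" in cfg:
        cfg["clinic_count_ranges"] = tuple(tuple(r) for r in cfg["clinic_count_ranges"])

    return TierSchedule(**cfg).validate()


# ---------------------------------------------------------------------------
# registry validation


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} registry is missing required field(s): {missing}")


def _check_coords(df: pd.DataFrame, what: str) -> None:
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]  # 1-based line incl. header
        raise ValidationError(
            f"{what} registry: coordinates out of range (lat in [-90,90], "
            f"lon in [-180,180]) at line(s) {rows}"
        )


def _check_unique_ids(df: pd.DataFrame, what: str) -> None:
    dup = df["id"].astype(str).duplicated(keep=False)
    if dup.any():
        ids = sorted(df.loc[dup, "id"].astype(str).unique())[:10]
        raise IntegrityError(f"{what} registry: duplicate id(s) {ids}")


def validate_facilities(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a facility registry DataFrame (copy returned)."""
    _require_columns(df, FACILITY_COLUMNS, "facility")
    df = df.loc[:, list(FACILITY_COLUMNS)].copy()
    df["id"] = df["id"].astype(str)
    _check_unique_ids(df, "facility")
    _check_coords(df, "facility")
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])

    bad_cat = ~df["category"].isin(CATEGORIES)
    if bad_cat.any():
        rows = [int(i) + 2 for i in df.index[bad_cat][:10]]
        raise ValidationError(
            f"facility registry: unknown category at line(s) {rows}; "
            f"expected one of {CATEGORIES}"
        )

    vol = pd.to_numeric(df["annual_volume"], errors="coerce")
    if vol.isna().any():
        n = int(vol.isna().sum())
        warnings.warn(
            f"{n} facility row(s) have missing annual_volume; treating as 0",
            stacklevel=2,
        )
        vol = vol.fillna(0)
    if (vol < 0).any():
        rows = [int(i) + 2 for i in df.index[vol < 0][:10]]
        raise ValidationError(f"facility registry: negative annual_volume at line(s) {rows}")
    df["annual_volume"] = vol.astype(int)
    df["district_id"] = df["district_id"].astype(str)
    df["name"] = df["name"].astype(str)
    return df.reset_index(drop=True)


def validate_labs(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a laboratory registry DataFrame (copy returned)."""
    _require_columns(df, LAB_COLUMNS, "laboratory")
    df = df.loc[:, list(LAB_COLUMNS)].copy()
    df["id"] = df["id"].astype(str)
    _check_unique_ids(df, "laboratory")
    _check_coords(df, "laboratory")
    df["latitude"] = pd.to_numeric(df["latitude"])
    df["longitude"] = pd.to_numeric(df["longitude"])

    tier = df["tier"].fillna("unassigned").astype(str).replace({"": "unassigned"})
    bad_tier = ~tier.isin(TIER_LABELS + ("unassigned",))
    if bad_tier.any():
        rows = [int(i) + 2 for i in df.index[bad_tier][:10]]
        raise ValidationError(
            f"laboratory registry: tier must be one of {TIER_LABELS} or "
            f"'unassigned' at line(s) {rows}"
        )
    df["tier"] = tier

    cap = pd.to_numeric(df["instrument_capacity_per_day"], errors="coerce").fillna(0)
    if (cap < 0).any():
        rows = [int(i) + 2 for i in df.index[cap < 0][:10]]
        raise ValidationError(f"laboratory registry: negative capacity at line(s) {rows}")
    df["instrument_capacity_per_day"] = cap.astype(int)

    gp = df["offers_general_pathology"]
    if gp.dtype != bool:
        gp = gp.astype(str).str.strip().str.lower().map(
            {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
        )
        if gp.isna().any():
            raise ValidationError(
                "laboratory registry: offers_general_pathology must be boolean"
            )
    df["offers_general_pathology"] = gp.astype(bool)
    df["district_id"] = df["district_id"].astype(str)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV / GeoJSON I/O


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "geojson"):
            raise SchemaError(f"format must be 'csv' or 'geojson', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "geojson" if suffix in (".geojson", ".json") else "csv"


def _read_geojson(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError(f"{path}: feature {i} is not a Point")
        lon, lat = geom["coordinates"][:2]
        props = dict(feat.get("properties") or {})
        props["longitude"], props["latitude"] = lon, lat
        rows.append(props)
    return pd.DataFrame(rows)


def _write_geojson(df: pd.DataFrame, path: str | Path) -> None:
    features = []
    for _, row in df.iterrows():
        props = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in row.items()
            if k not in ("latitude", "longitude")
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["longitude"]), float(row["latitude"])],
                },
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_facilities(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a facility registry from CSV or GeoJSON and validate it."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    raw = pd.read_csv(path) if fmt == "csv" else _read_geojson(path)
    return validate_facilities(raw)


def write_facilities(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    df = df.loc[:, list(FACILITY_COLUMNS)]
    if fmt == "csv":
        df.to_csv(path, index=False)
    else:
        _write_geojson(df, path)


def read_labs(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a laboratory registry from CSV or GeoJSON and validate it."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    raw = pd.read_csv(path) if fmt == "csv" else _read_geojson(path)
    return validate_labs(raw)


def write_labs(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    df = df.loc[:, list(LAB_COLUMNS)]
    if fmt == "csv":
        df.to_csv(path, index=False)
    else:
        _write_geojson(df, path)


def cd4_labs(labs: pd.DataFrame) -> pd.DataFrame:
    """The subset of a laboratory registry that performs CD4 testing.

    General-pathology-only sites (placement candidates for new Tier-2/3
    services) carry ``instrument_capacity_per_day == 0``.
    """
    return labs[labs["instrument_capacity_per_day"] > 0].reset_index(drop=True)
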