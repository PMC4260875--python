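"""Distances, facility-to-laboratory assignment and service-precinct coverage.

A *service precinct* is the circular catchment (default 100 km radius)
around a testing laboratory.  Each referring facility is assigned to its
nearest laboratory; facilities farther than the precinct radius from every
laboratory are coverage gaps.  Distances default to great-circle
(haversine) kilometres on a mean-Earth sphere; a planar equirectangular
approximation is available for comparison since precinct radii of
100-400 km are short enough for either convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import TierSchedule

#: Mean Earth radius (km), IUGG value.
EARTH_RADIUS_KM = 6371.0088

#: Distance tolerance (km) below which two candidate laboratories are
#: considered tied and the lexicographically smallest id wins.
TIE_TOL_KM = 1e-9


def _check_latlon(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("coordinates out of range: |lat| <= 90, |lon| <= 180")


def great_circle_km(a, b) -> float:
    """Great-circle distance in km between two (lat, lon) points (haversine)."""
    (lat1, lon1), (lat2, lon2) = a, b
    return float(
        _pairwise_haversine(
            np.array([lat1], float),
            np.array([lon1], float),
            np.array([lat2], float),
            np.array([lon2], float),
        )[0, 0]
    )


def _pairwise_haversine(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Pairwise haversine matrix, shape (len(points1), len(points2))."""
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    p1, l1 = np.radians(lat1)[:, None], np.radians(lon1)[:, None]
    p2, l2 = np.radians(lat2)[None, :], np.radians(lon2)[None, :]
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _pairwise_planar(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Equirectangular planar approximation about the joint mean latitude."""
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    lat0 = np.radians(np.mean(np.concatenate([lat1, lat2])))
    kx = np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(lat0)
    ky = np.pi / 180.0 * EARTH_RADIUS_KM
    dx = (lon2[None, :] - lon1[:, None]) * kx
    dy = (lat2[None, :] - lat1[:, None]) * ky
    return np.hypot(dx, dy)


def pairwise_distances(
    points_a: pd.DataFrame, points_b: pd.DataFrame, method: str = "haversine"
) -> np.ndarray:
    """Distance matrix (km) between the rows of two lat/lon DataFrames."""
    fn = {"haversine": _pairwise_haversine, "planar": _pairwise_planar}.get(method)
    if fn is None:
        raise ValidationError(f"unknown distance method {method!r}")
    return fn(
        points_a["latitude"].to_numpy(float),
        points_a["longitude"].to_numpy(float),
        points_b["latitude"].to_numpy(float),
        points_b["longitude"].to_numpy(float),
    )


def assign_nearest(
    facilities: pd.DataFrame,
    labs: pd.DataFrame,
    schedule: TierSchedule,
    method: str = "haversine",
) -> pd.DataFrame:
    """Assign each facility to its nearest laboratory.

    Returns a DataFrame with columns ``facility_id, lab_id, distance_km,
    covered`` where ``covered`` means the distance does not exceed the
    schedule's precinct radius.  Exact ties (within 1e-9 km) go to the
    lexicographically smallest laboratory id.
    """
    if len(labs) == 0:
        raise ValidationError("cannot assign facilities: laboratory registry is empty")
    labs = labs.sort_values("id", kind="stable").reset_index(drop=True)
    dmat = pairwise_distances(facilities, labs, method=method)
    dmin = dmat.min(axis=1)
    # first (smallest-id, labs pre-sorted) lab within tolerance of the minimum
    idx = np.argmax(dmat <= (dmin[:, None] + TIE_TOL_KM), axis=1)
    dist = dmat[np.arange(len(facilities)), idx]
    return pd.DataFrame(
        {
            "facility_id": facilities["id"].to_numpy(),
            "lab_id": labs["id"].to_numpy()[idx],
            "distance_km": dist,
            "covered": dist <= schedule.radius_km,
        }
    )


@dataclass
class CoverageReport:
    """Summary of service-precinct coverage for one assignment run."""

    fraction_covered: float
    fraction_covered_volume: float
    uncovered_ids: list[str]
    per_district: pd.DataFrame  # district_id, n_facilities, mean_km, max_km
    overserviced_pairs: list[tuple[str, str, float]]
    radius_km: float
    method: str


def coverage_report(
    assignments: pd.DataFrame,
    facilities: pd.DataFrame,
    labs: pd.DataFrame,
    schedule: TierSchedule,
    method: str = "haversine",
) -> CoverageReport:
    """Compute facility- and volume-weighted coverage, gaps and over-service.

    Over-serviced areas are flagged as pairs of laboratories lying within
    one precinct radius of each other (candidates for consolidation).
    """
    merged = assignments.merge(
        facilities[["id", "annual_volume", "district_id"]],
        left_on="facility_id",
        right_on="id",
        validate="one_to_one",
    )
    n = len(merged)
    frac = float(merged["covered"].sum()) / n if n else 1.0
    total_vol = int(merged["annual_volume"].sum())
    frac_vol = (
        float(merged.loc[merged["covered"], "annual_volume"].sum()) / total_vol
        if total_vol
        else 1.0
    )
    uncovered = sorted(merged.loc[~merged["covered"], "facility_id"].tolist())

    per_district = (
        merged.groupby("district_id", as_index=False)
        .agg(
            n_facilities=("facility_id", "size"),
            mean_km=("distance_km", "mean"),
            max_km=("distance_km", "max"),
        )
        .sort_values("district_id", kind="stable")
        .reset_index(drop=True)
    )

    pairs: list[tuple[str, str, float]] = []
    if len(labs) > 1:
        labs_sorted = labs.sort_values("id", kind="stable").reset_index(drop=True)
        dmat = pairwise_distances(labs_sorted, labs_sorted, method=method)
        ids = labs_sorted["id"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if dmat[i, j] <= schedule.radius_km:
                    pairs.append((ids[i], ids[j], float(dmat[i, j])))

    return CoverageReport(
        fraction_covered=frac,
        fraction_covered_volume=frac_vol,
        uncovered_ids=uncovered,
        per_district=per_district,
        overserviced_pairs=pairs,
        radius_km=schedule.radius_km,
        method=method,
    )


def precincts_geojson(
    labs: pd.DataFrame, radius_km: float, n_segments: int = 64
) -> dict:
    """Service precincts as a GeoJSON FeatureCollection of circle polygons.

    Circles are small-circle approximations: ``n_segments``-vertex polygons
    offset from each laboratory in geographic coordinates.
    """
    ang = np.linspace(0.0, 2 * np.pi, n_segments + 1)
    features = []
    for _, lab in labs.iterrows():
        lat0, lon0 = float(lab["latitude"]), float(lab["longitude"])
        dlat = np.degrees(radius_km / EARTH_RADIUS_KM) * np.cos(ang)
        dlon = (
            np.degrees(radius_km / EARTH_RADIUS_KM)
            * np.sin(ang)
            / np.cos(np.radians(lat0))
        )
        ring = [[float(lon0 + x), float(lat0 + y)] for x, y in zip(dlon, dlat)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"lab_id": str(lab["id"]), "radius_km": radius_km},
            }
        )
    return {"type": "FeatureCollection", "features": features}
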