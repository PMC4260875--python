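"""Tier classification, capacity checking and the parent-support graph.

A testing site's tier is a step function of its daily sample load alone
(annual assigned demand / working days), judged against the schedule's
inclusive upper volume breaks.  The advisory clinic-count ranges are a
consistency annotation, not a constraint.  Every Tier-1/2 site is linked
to its nearest Tier-3+ laboratory, which acts as its *parent* for quality
control, training and equipment support; co-located high-volume (T4/T5)
laboratories whose combined demand exceeds the super-laboratory threshold
are reported as consolidation candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import pairwise_distances
from .errors import ValidationError
from .model import TierSchedule


@dataclass(frozen=True)
class TierAssignment:
    """One site's tier classification."""

    lab_id: str | None
    tier: int  # 1..5
    daily_volume: float  # samples/day
    clinics_served: int
    clinic_count_consistent: bool
    capacity_margin: float  # schedule instrument capacity - daily demand


def classify_tier(
    daily_volume: float,
    clinics_served: int,
    schedule: TierSchedule,
    lab_id: str | None = None,
    n_instruments: int = 1,
) -> TierAssignment:
    """Classify a site by daily volume against the schedule's tier breaks."""
    if daily_volume < 0:
        raise ValidationError(f"daily_volume must be >= 0, got {daily_volume}")
    if daily_volume == 0:
        warnings.warn(
            f"site {lab_id or '<unnamed>'} has zero demand; classified Tier 1",
            stacklevel=2,
        )
    tier = schedule.tier_of(daily_volume)
    lo, hi = schedule.clinic_count_ranges[tier - 1]
    return TierAssignment(
        lab_id=lab_id,
        tier=tier,
        daily_volume=daily_volume,
        clinics_served=int(clinics_served),
        clinic_count_consistent=lo <= clinics_served <= hi,
        capacity_margin=schedule.instrument_capacity[tier - 1] * n_instruments
        - daily_volume,
    )


def tier_labs(
    assignments: pd.DataFrame,
    facilities: pd.DataFrame,
    labs: pd.DataFrame,
    schedule: TierSchedule,
) -> pd.DataFrame:
    """Classify every laboratory from its assigned facility demand.

    Daily volume is the annual volume of the facilities assigned to the
    laboratory divided by the schedule's working days.  Labs with no
    assigned facilities appear with zero demand (Tier 1, flagged by the
    zero-demand warning from :func:`classify_tier`).

    Returns columns ``lab_id, tier, daily_volume, clinics_served,
    clinic_count_consistent, capacity_margin``.
    """
    demand = (
        assignments.merge(
            facilities[["id", "annual_volume"]],
            left_on="facility_id",
            right_on="id",
        )
        .groupby("lab_id")
        .agg(annual=("annual_volume", "sum"), clinics=("facility_id", "size"))
    )
    rows = []
    for lab_id in labs["id"].astype(str):
        annual = int(demand["annual"].get(lab_id, 0))
        clinics = int(demand["clinics"].get(lab_id, 0))
        daily = annual / schedule.working_days_per_year
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-demand labs are expected here
            ta = classify_tier(daily, clinics, schedule, lab_id=lab_id)
        rows.append(ta)
    return pd.DataFrame(
        {
            "lab_id": [t.lab_id for t in rows],
            "tier": [t.tier for t in rows],
            "daily_volume": [t.daily_volume for t in rows],
            "clinics_served": [t.clinics_served for t in rows],
            "clinic_count_consistent": [t.clinic_count_consistent for t in rows],
            "capacity_margin": [t.capacity_margin for t in rows],
        }
    )


def capacity_check(
    tier_assignments: pd.DataFrame,
    schedule: TierSchedule,
    n_instruments: pd.Series | dict | int = 1,
) -> pd.DataFrame:
    """Compare per-site instrument capacity with daily demand.

    ``capacity = schedule.instrument_capacity[tier] * n_instruments``;
    sites with negative margin (demand exceeding capacity) are flagged.
    ``n_instruments`` may be a scalar or a per-lab mapping / Series.
    """
    bad = ~tier_assignments["tier"].isin(range(1, 7))
    if bad.any():
        raise ValidationError(
            f"unknown tier(s): {sorted(tier_assignments.loc[bad, 'tier'].unique())}"
        )
    if isinstance(n_instruments, int):
        n_inst = pd.Series(n_instruments, index=tier_assignments["lab_id"])
    else:
        n_inst = pd.Series(n_instruments).reindex(tier_assignments["lab_id"]).fillna(1)
    caps = np.array(schedule.instrument_capacity)[
        tier_assignments["tier"].to_numpy() - 1
    ] * n_inst.to_numpy()
    demand = tier_assignments["daily_volume"].to_numpy(float)
    margin = caps - demand
    return pd.DataFrame(
        {
            "lab_id": tier_assignments["lab_id"].to_numpy(),
            "capacity": caps,
            "demand": demand,
            "margin": margin,
            "flag": margin < 0,
        }
    )


def build_support_graph(
    tier_assignments: pd.DataFrame,
    locations: pd.DataFrame,
    method: str = "haversine",
) -> pd.DataFrame:
    """Link every Tier-1/2 site to its nearest Tier-3+ parent laboratory.

    ``locations`` must carry ``id, latitude, longitude`` for every site in
    ``tier_assignments``.  The result is a forest: each child has exactly
    one parent, and a parent's tier is strictly higher than its child's.

    Returns columns ``child_id, parent_id, child_tier, parent_tier,
    distance_km``.
    """
    ta = tier_assignments.merge(
        locations[["id", "latitude", "longitude"]],
        left_on="lab_id",
        right_on="id",
        validate="one_to_one",
    )
    children = ta[ta["tier"] <= 2].reset_index(drop=True)
    parents = ta[ta["tier"] >= 3].sort_values("lab_id", kind="stable").reset_index(drop=True)
    if len(children) == 0:
        return pd.DataFrame(
            columns=["child_id", "parent_id", "child_tier", "parent_tier", "distance_km"]
        )
    if len(parents) == 0:
        orphans = sorted(children["lab_id"].tolist())
        raise ValidationError(
            f"no Tier-3+ site available to parent Tier-1/2 sites: {orphans}"
        )
    dmat = pairwise_distances(children, parents, method=method)
    idx = dmat.argmin(axis=1)
    return pd.DataFrame(
        {
            "child_id": children["lab_id"].to_numpy(),
            "parent_id": parents["lab_id"].to_numpy()[idx],
            "child_tier": children["tier"].to_numpy(),
            "parent_tier": parents["tier"].to_numpy()[idx],
            "distance_km": dmat[np.arange(len(children)), idx],
        }
    )


def superlab_candidates(
    tier_assignments: pd.DataFrame,
    locations: pd.DataFrame,
    schedule: TierSchedule,
    method: str = "haversine",
) -> list[dict]:
    """Clusters of co-located T4/T5 labs eligible for consolidation.

    High-tier laboratories within one precinct radius of each other are
    joined into connected components; components of two or more labs whose
    combined daily demand exceeds the super-laboratory threshold are
    returned as candidate clusters (lab ids sorted, with combined demand).
    """
    hi = tier_assignments[tier_assignments["tier"] >= 4].merge(
        locations[["id", "latitude", "longitude"]],
        left_on="lab_id",
        right_on="id",
        validate="one_to_one",
    )
    if len(hi) < 2:
        return []
    hi = hi.sort_values("lab_id", kind="stable").reset_index(drop=True)
    dmat = pairwise_distances(hi, hi, method=method)
    n = len(hi)

    # union-find over the within-radius adjacency
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= schedule.radius_km:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    clusters = []
    for members in comps.values():
        if len(members) < 2:
            continue
        demand = float(hi.loc[members, "daily_volume"].sum())
        if demand > schedule.superlab_break:
            clusters.append(
                {
                    "lab_ids": sorted(hi.loc[members, "lab_id"].tolist()),
                    "combined_daily_volume": demand,
                }
            )
    clusters.sort(key=lambda c: c["lab_ids"])
    return clusters
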