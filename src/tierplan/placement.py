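"""Greedy maximal-covering placement of new decentralised testing sites.

Facilities left outside every existing service precinct are closed off by
proposing new Tier-2/3 services inside general-pathology laboratories
(which already have buildings, staff and courier logistics) and on-site
Tier-1 point-of-care testing at whatever remains unreachable.  The siting
itself is a greedy maximal-covering heuristic: repeatedly pick the
candidate that newly covers the most facilities.  Greedy is transparent,
deterministic and carries the classical ``ln n + 1`` approximation
guarantee; exact set-cover optimisation is out of scope.

Each general-pathology candidate is considered in two roles — a Tier-2
POC hub covering facilities within the hub radius (default 20 km) and a
community-laboratory role covering the full precinct radius (default
100 km).  The tier finally proposed for a chosen site comes from
classifying the daily volume it would absorb, so a low-volume pick in the
wide role may still be proposed as a Tier-2 (or even Tier-1) service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .coverage import pairwise_distances
from .errors import ValidationError
from .model import TierSchedule
from .tiering import classify_tier


@dataclass(frozen=True)
class PlacementSite:
    """One proposed site: the candidate chosen and what it absorbs."""

    candidate_id: str
    role_radius_km: float
    proposed_tier: int
    covered_facility_ids: tuple[str, ...]
    projected_daily_volume: float
    projected_annual_volume: int


@dataclass
class PlacementPlan:
    """Ordered greedy site selections plus the residual on-site Tier-1 set."""

    sites: list[PlacementSite] = field(default_factory=list)
    residual_t1_ids: list[str] = field(default_factory=list)


def greedy_cover(
    cover_sets: dict[str, set[str]],
    weights: dict[str, int] | None = None,
    min_gain: int = 2,
    radii: dict[str, float] | None = None,
) -> tuple[list[tuple[str, set[str]]], set[str]]:
    """Greedy maximal covering over abstract coverage sets.

    Repeatedly selects the candidate covering the most still-uncovered
    elements; ties break on the largest covered weight, then the smallest
    role radius (when ``radii`` is given), then the smallest candidate id.
    Stops when the best gain drops below ``min_gain``.

    Returns the ordered selections as ``(candidate_id, newly_covered)``
    pairs and the set of elements left uncovered.
    """
    weights = weights or {}
    uncovered: set[str] = set().union(*cover_sets.values()) if cover_sets else set()
    selections: list[tuple[str, set[str]]] = []
    while uncovered:
        best = None
        for cand_id in sorted(cover_sets):
            gain_set = cover_sets[cand_id] & uncovered
            gain = len(gain_set)
            if gain == 0:
                continue
            w = sum(weights.get(e, 0) for e in gain_set)
            r = radii.get(cand_id, 0.0) if radii else 0.0
            key = (-gain, -w, r, cand_id)
            if best is None or key < best[0]:
                best = (key, cand_id, gain_set)
        if best is None or len(best[2]) < min_gain:
            break
        _, cand_id, gain_set = best
        selections.append((cand_id, gain_set))
        uncovered -= gain_set
    return selections, uncovered


def propose_sites(
    uncovered: pd.DataFrame,
    candidates: pd.DataFrame,
    schedule: TierSchedule,
    min_gain: int = 2,
    method: str = "haversine",
) -> PlacementPlan:
    """Propose new testing sites covering the currently uncovered facilities.

    ``uncovered`` is a facility registry slice (uncovered facilities only);
    ``candidates`` a laboratory registry whose ``offers_general_pathology``
    sites become Tier-2/3 hosts.  Facilities no selected candidate reaches
    become on-site Tier-1 services absorbing their own volume.
    """
    plan = PlacementPlan()
    if len(uncovered) == 0:
        return plan
    cands = candidates[candidates["offers_general_pathology"]].reset_index(drop=True)

    cover_sets: dict[str, set[str]] = {}
    radii: dict[str, float] = {}
    cand_of: dict[str, str] = {}
    if len(cands) > 0:
        dmat = pairwise_distances(cands, uncovered, method=method)
        fac_ids = uncovered["id"].astype(str).to_numpy()
        for i, cand_id in enumerate(cands["id"].astype(str)):
            for role, radius in (("hub", schedule.t2_radius_km), ("lab", schedule.radius_km)):
                within = set(fac_ids[dmat[i] <= radius])
                if within:
                    key = f"{cand_id}@{role}"
                    cover_sets[key] = within
                    radii[key] = radius
                    cand_of[key] = cand_id

    vols = dict(zip(uncovered["id"].astype(str), uncovered["annual_volume"].astype(int)))
    selections, residual = greedy_cover(cover_sets, vols, min_gain=min_gain, radii=radii)
    # facilities outside every candidate's reach never enter a cover set
    residual |= set(vols) - set().union(set(), *cover_sets.values())

    for key, gain_set in selections:
        annual = int(sum(vols[f] for f in gain_set))
        daily = annual / schedule.working_days_per_year
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-volume picks are legal
            tier = classify_tier(daily, len(gain_set), schedule).tier
        plan.sites.append(
            PlacementSite(
                candidate_id=cand_of[key],
                role_radius_km=radii[key],
                proposed_tier=tier,
                covered_facility_ids=tuple(sorted(gain_set)),
                projected_daily_volume=daily,
                projected_annual_volume=annual,
            )
        )
    plan.residual_t1_ids = sorted(residual)
    return plan


def plan_summary(
    plan: PlacementPlan,
    schedule: TierSchedule,
    uncovered: pd.DataFrame | None = None,
    total_annual: int | None = None,
) -> pd.DataFrame:
    """Per-tier proposed site counts and absorbed annual volumes.

    Residual facilities count as one on-site Tier-1 service each, absorbing
    their own annual volume (requires ``uncovered`` to look volumes up).
    If ``total_annual`` is given, each tier's share of the national volume
    is included.
    """
    counts = {k: 0 for k in range(1, 6)}
    volumes = {k: 0 for k in range(1, 6)}
    for site in plan.sites:
        counts[site.proposed_tier] += 1
        volumes[site.proposed_tier] += site.projected_annual_volume
    if plan.residual_t1_ids:
        if uncovered is None:
            raise ValidationError(
                "plan has residual on-site Tier-1 facilities; pass the uncovered "
                "registry so their volumes can be attributed"
            )
        vols = dict(zip(uncovered["id"].astype(str), uncovered["annual_volume"].astype(int)))
        counts[1] += len(plan.residual_t1_ids)
        volumes[1] += int(sum(vols[f] for f in plan.residual_t1_ids))
    out = pd.DataFrame(
        {
            "tier": [f"T{k}" for k in range(1, 6)],
            "n_sites": [counts[k] for k in range(1, 6)],
            "annual_volume": [volumes[k] for k in range(1, 6)],
        }
    )
    if total_annual:
        out["share_of_national"] = out["annual_volume"] / float(total_annual)
    return out
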