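"""Scenario cost model: per-tier annual volumes x per-test prices.

All money is integer US cents and all volumes integer tests/year, so
scenario totals are exact and independent of summation order.  Two named
scenarios compare ways of extending a laboratory network to full national
coverage:

* ``widespread_poc`` — the entire decentralised extension volume (the
  Tier-1..3 share of national demand) is tested at point-of-care Tier-1
  prices, on top of the existing Tier-4/5 network at their own prices.
* ``full_itsdm`` — each tier tests its own share at its own price.

The difference between the two is the programme saving from consolidating
point-of-care testing into hubs and community laboratories; algebraically
it equals ``V2*(c1-c2) + V3*(c1-c3)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .model import TierSchedule

#: Default per-tier shares of annual national volume (T1..T5).
DEFAULT_TIER_SHARES: tuple[float, ...] = (0.02, 0.03, 0.10, 0.15, 0.70)

#: Default annual national test volume.
DEFAULT_TOTAL_ANNUAL = 3_900_000


def largest_remainder_apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder (Hamilton) method: floor the exact quotas, then hand
    the remaining units to the largest fractional remainders, ties going to
    the smallest index.  The result always sums exactly to ``total``.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        raise ValidationError("weights must be non-empty")
    if np.any(w < 0) or not np.isfinite(w).all():
        raise ValidationError("weights must be finite and non-negative")
    s = w.sum()
    if s <= 0:
        raise ValidationError("weights must have a positive sum")
    quota = total * (w / s)
    base = np.floor(quota).astype(np.int64)
    short = int(total - base.sum())
    # stable sort on negative remainder -> ties resolved by smallest index
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return [int(x) for x in base]


def allocate_volumes(
    total_annual: int, shares: Sequence[float] | None = None
) -> list[int]:
    """Split an annual national volume into per-tier integer volumes.

    ``shares`` must sum to 1 (within 1e-9); rounding is largest-remainder
    so the tier volumes sum exactly to ``total_annual``.
    """
    if shares is None:
        shares = DEFAULT_TIER_SHARES
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValidationError(f"tier shares must sum to 1, got {sum(shares)!r}")
    if total_annual < 0:
        raise ValidationError("total_annual must be non-negative")
    return largest_remainder_apportion(int(total_annual), shares)


@dataclass(frozen=True)
class CostScenario:
    """Per-tier annual volumes costed at per-tier prices (exact cents)."""

    name: str
    volumes: tuple[int, ...]  # T1..T5 tests/year
    unit_cost_cents: tuple[int, ...]  # T1..T5
    tier_cost_cents: tuple[int, ...]  # T1..T5
    total_cents: int
    total_zar_cents: int

    @property
    def total_usd(self) -> float:
        return self.total_cents / 100.0

    @property
    def total_zar(self) -> float:
        return self.total_zar_cents / 100.0

    @property
    def tier_cost_usd(self) -> tuple[float, ...]:
        return tuple(c / 100.0 for c in self.tier_cost_cents)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tier": [f"T{k}" for k in range(1, 6)],
                "annual_volume": self.volumes,
                "unit_cost_usd": [c / 100.0 for c in self.unit_cost_cents],
                "annual_cost_usd": self.tier_cost_usd,
            }
        )


def to_zar_cents(usd_cents: int, schedule: TierSchedule) -> int:
    """Convert integer US cents to integer ZAR cents at the schedule rate."""
    rate = schedule.zar_per_usd
    if rate <= 0:
        raise ConfigError("zar_per_usd must be positive")
    if float(rate).is_integer():
        return int(usd_cents) * int(rate)
    return int(round(usd_cents * rate))


def to_zar(usd: float, schedule: TierSchedule) -> float:
    """Convert a USD amount to ZAR at the schedule exchange rate."""
    if schedule.zar_per_usd <= 0:
        raise ConfigError("zar_per_usd must be positive")
    return usd * schedule.zar_per_usd


def scenario_cost(
    volumes: Sequence[int], schedule: TierSchedule, name: str = "custom"
) -> CostScenario:
    """Cost a per-tier volume vector (T1..T5, optionally +T6) exactly.

    A sixth element, if present, must be zero: the reference tier carries
    no per-test price and may not receive testing volume.
    """
    vols = [int(v) for v in volumes]
    if any(v < 0 for v in vols):
        raise ValidationError("tier volumes must be non-negative")
    if len(vols) == 6:
        if vols[5] != 0:
            raise ValidationError(
                "Tier 6 carries no per-test cost and cannot receive testing volume"
            )
        vols = vols[:5]
    if len(vols) != 5:
        raise ValidationError(f"expected 5 per-tier volumes (T1..T5), got {len(vols)}")
    costs = schedule.cost_per_test_cents
    tier_cost = tuple(v * c for v, c in zip(vols, costs))
    total = sum(tier_cost)
    return CostScenario(
        name=name,
        volumes=tuple(vols),
        unit_cost_cents=costs,
        tier_cost_cents=tier_cost,
        total_cents=total,
        total_zar_cents=to_zar_cents(total, schedule),
    )


def full_itsdm_scenario(
    schedule: TierSchedule,
    total_annual: int = DEFAULT_TOTAL_ANNUAL,
    shares: Sequence[float] | None = None,
) -> CostScenario:
    """Each tier tests its allocated share at its own per-test price."""
    return scenario_cost(allocate_volumes(total_annual, shares), schedule, "full_itsdm")


def widespread_poc_scenario(
    schedule: TierSchedule,
    total_annual: int = DEFAULT_TOTAL_ANNUAL,
    shares: Sequence[float] | None = None,
) -> CostScenario:
    """The whole Tier-1..3 extension volume priced at the Tier-1 POC rate.

    Built from the same per-tier allocation as ``full_itsdm``: the T1+T2+T3
    volumes collapse onto Tier 1 (no hub or community services), while the
    existing Tier-4/5 network keeps its own volumes and prices.
    """
    v = allocate_volumes(total_annual, shares)
    collapsed = [v[0] + v[1] + v[2], 0, 0, v[3], v[4]]
    return scenario_cost(collapsed, schedule, "widespread_poc")


@dataclass(frozen=True)
class ScenarioComparison:
    """Saving of scenario B relative to scenario A, plus unit-cost ratios."""

    scenario_a: str
    scenario_b: str
    saving_cents: int  # total(A) - total(B)
    saving_zar_cents: int
    unit_cost_table: pd.DataFrame  # tier_a, tier_b, diff_usd, ratio, premium_pct

    @property
    def saving_usd(self) -> float:
        return self.saving_cents / 100.0

    @property
    def saving_zar(self) -> float:
        return self.saving_zar_cents / 100.0


def unit_cost_ratio_table(schedule: TierSchedule) -> pd.DataFrame:
    """Pairwise per-test cost comparisons between tiers.

    For each ordered pair (a, b): ``diff_usd = c_a - c_b``, ``ratio =
    c_a / c_b`` and ``premium_pct = 100 * (c_a - c_b) / c_b``.  E.g. with
    the default schedule, T3 vs T5 shows a $2.05 difference (a 38% premium)
    and T3 vs T1 a ratio of 0.23.
    """
    costs = schedule.cost_per_test_cents
    rows = []
    for a in range(5):
        for b in range(5):
            if a == b:
                continue
            rows.append(
                {
                    "tier_a": f"T{a + 1}",
                    "tier_b": f"T{b + 1}",
                    "diff_usd": (costs[a] - costs[b]) / 100.0,
                    "ratio": costs[a] / costs[b],
                    "premium_pct": 100.0 * (costs[a] - costs[b]) / costs[b],
                }
            )
    return pd.DataFrame(rows)


def compare_scenarios(
    a: CostScenario, b: CostScenario, schedule: TierSchedule
) -> ScenarioComparison:
    """Absolute saving (USD and ZAR) of choosing scenario ``b`` over ``a``."""
    saving = a.total_cents - b.total_cents
    return ScenarioComparison(
        scenario_a=a.name,
        scenario_b=b.name,
        saving_cents=saving,
        saving_zar_cents=to_zar_cents(saving, schedule),
        unit_cost_table=unit_cost_ratio_table(schedule),
    )
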